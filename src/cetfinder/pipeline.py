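"""End-to-end orchestration: shortlist -> distances -> sweep -> null -> CETs."""
from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .aggregate import (ConditionMatrix, MasterList, build_condition_matrix,
                        build_master, enriched_cets, recluster_master)
from .cluster import ClusterAssignment, sweep
from .germline import GermlineCdrTable, GermlineNtTable
from .io import shortlist_top
from .metric import DistanceMatrix, pairwise_matrix
from .nullmodel import ElementPools, NullTrial, run_null
from .repertoire import Repertoire
from .significance import Cet, PipelineConfig, call_cets, significant_cets


@dataclass
class SampleResult:
    """Everything computed for one sample's shortlist."""

    sample_id: str
    shortlist: Repertoire
    matrix: DistanceMatrix
    assignments: List[ClusterAssignment]
    trials: List[NullTrial]
    cets: List[Cet]
    config: PipelineConfig
    timings: Dict[str, float] = field(default_factory=dict)

    @property
    def significant(self) -> List[Cet]:
        return significant_cets(self.cets)


def run_sample(rep: Repertoire, pools: ElementPools,
               cdr_table: GermlineCdrTable, nt_table: GermlineNtTable,
               config: PipelineConfig,
               trials: Optional[List[NullTrial]] = None,
               seed: Optional[int] = None) -> SampleResult:
    """Full CET analysis of one sample.

    ``trials`` may be supplied to reuse already-generated null trials (only
    valid when they were produced under the same config and an identical
    observed frequency multiset).
    """
    timings: Dict[str, float] = {}
    t0 = time.perf_counter()
    short = shortlist_top(rep, config.shortlist_n)
    timings["shortlist"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    matrix = pairwise_matrix(short, cdr_table, config.tcrdist)
    timings["pairwise"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    assignments = sweep(matrix, config.ladder, config.linkage)
    timings["sweep"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if trials is None:
        trials = run_null(pools, list(short.frequencies), config.ladder,
                          config.n_trials,
                          config.seed if seed is None else seed,
                          nt_table, cdr_table, params=config.tcrdist,
                          linkage=config.linkage, mode=config.null_mode,
                          min_members=config.min_members)
    timings["null"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cets = call_cets(assignments, short, trials, config)
    timings["significance"] = time.perf_counter() - t0

    return SampleResult(sample_id=rep.sample_id, shortlist=short,
                        matrix=matrix, assignments=assignments, trials=trials,
                        cets=cets, config=config, timings=timings)


def compare_conditions(results: Sequence[SampleResult],
                       repertoires: Sequence[Repertoire],
                       reference: str, cdr_table: GermlineCdrTable,
                       config: PipelineConfig,
                       ) -> Tuple[MasterList, List[Cet], ConditionMatrix,
                                  List[Tuple[Cet, Dict[str, float]]]]:
    """Aggregate significant CETs across samples, recluster at the ladder
    maximum, and compute per-condition fold enrichment vs the reference."""
    chains = {r.shortlist.chain for r in results}
    if len(chains) != 1:
        raise ValueError(f"runs must share one chain, got {sorted(chains)}")
    master = build_master(c for r in results for c in r.significant)
    final = recluster_master(master, config.ladder.max, cdr_table,
                             config.tcrdist, config.linkage)
    cond = build_condition_matrix(master, repertoires)
    flagged = enriched_cets(final, cond, reference,
                            cutoff=config.enrichment_cutoff,
                            min_members=config.report_min_members)
    return master, final, cond, flagged
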