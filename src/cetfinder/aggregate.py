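"""Cross-threshold/cross-sample CET aggregation, enrichment, and deep queries.

Significant clusters found at any threshold (and in any sample) are combined
into a deduplicated master clonotype list and reclustered at the maximum
threshold for final reporting. Per-condition fold enrichment of each final
CET is the geometric mean over members of frequency ratios versus a
reference (antigen-negative) condition, with undetected reference members
floored at a pseudo-frequency equal to the detection limit of the reference
sample's sequencing depth. CET members can be queried against deep
uncultured repertoires by exact nucleotide-level clonotype identity
(V call, J call, CDR3 nucleotide sequence).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cluster import build_dendrogram, cut_at_threshold
from .germline import GermlineCdrTable
from .metric import TcrdistParams, pairwise_matrix
from .nullmodel import geometric_mean
from .repertoire import Clonotype, ClonotypeKey, Repertoire
from .significance import Cet

Provenance = Tuple[str, int, str]  # (sample_id, threshold, cet_id)


@dataclass(frozen=True)
class MasterList:
    """Deduplicated clonotypes drawn from significant CETs, with provenance."""

    clonotypes: Tuple[Clonotype, ...]
    provenance: Dict[ClonotypeKey, Tuple[Provenance, ...]]

    def __len__(self) -> int:
        return len(self.clonotypes)

    def keys(self) -> Tuple[ClonotypeKey, ...]:
        return tuple(c.key for c in self.clonotypes)


def build_master(cets: Iterable[Cet]) -> MasterList:
    """Union of member clonotypes across CETs, deduplicated on clonotype key."""
    seen: Dict[ClonotypeKey, Clonotype] = {}
    prov: Dict[ClonotypeKey, List[Provenance]] = {}
    for cet in cets:
        for member in cet.members:
            if member.key not in seen:
                seen[member.key] = member
            prov.setdefault(member.key, []).append(
                (cet.sample_id, cet.threshold, cet.cet_id))
    ordered = sorted(seen.values(), key=lambda c: c.key)
    return MasterList(clonotypes=tuple(ordered),
                      provenance={k: tuple(v) for k, v in prov.items()})


def recluster_master(master: MasterList, t_max: int, table: GermlineCdrTable,
                     params: TcrdistParams = TcrdistParams(),
                     linkage: str = "complete",
                     id_prefix: str = "CET") -> List[Cet]:
    """Final display CETs: recluster the master list at the ladder maximum.

    Conserves clonotypes (no member gained or lost, only regrouped); final
    ids are assigned in descending (size, geometric mean frequency) order.
    """
    if len(master) == 0:
        return []
    rep = Repertoire.build(master.clonotypes, sample_id="master",
                           renormalize=False)
    matrix = pairwise_matrix(rep, table, params)
    dendro = build_dendrogram(matrix, linkage=linkage, stop_height=float(t_max))
    assign = cut_at_threshold(dendro, t_max)
    clons = rep.clonotypes
    groups = []
    for members in assign.clusters:
        member_clons = tuple(clons[m] for m in members)
        freqs = [c.frequency for c in member_clons]
        gmean = geometric_mean(freqs) if min(freqs) > 0 else 0.0
        groups.append((member_clons, gmean))
    groups.sort(key=lambda g: (-len(g[0]), -g[1], g[0][0].key))
    out = []
    for rank, (member_clons, gmean) in enumerate(groups, start=1):
        out.append(Cet(cet_id=f"{id_prefix}-{rank:03d}", threshold=t_max,
                       members=member_clons, n_members=len(member_clons),
                       geo_mean_freq=gmean, p_value=None, n_exceed=0,
                       n_trials=0, significant=True,
                       sample_id="master", condition=""))
    return out


@dataclass
class ConditionMatrix:
    """Master-list clonotype frequencies across samples, grouped by condition."""

    frequencies: pd.DataFrame  # rows: clonotype keys; columns: sample ids
    condition_of: Dict[str, str]  # sample id -> condition label
    total_reads: Dict[str, int]  # sample id -> depth (for the pseudo floor)

    def samples_for(self, condition: str) -> List[str]:
        return [s for s, c in self.condition_of.items() if c == condition]

    @property
    def conditions(self) -> List[str]:
        seen = []
        for c in self.condition_of.values():
            if c not in seen:
                seen.append(c)
        return seen


def build_condition_matrix(master: MasterList,
                           repertoires: Sequence[Repertoire]) -> ConditionMatrix:
    """Frequencies of master-list clonotypes in each sample (0 if undetected)."""
    keys = master.keys()
    data = {}
    condition_of = {}
    totals = {}
    for rep in repertoires:
        lookup = {c.key: c.frequency for c in rep}
        data[rep.sample_id] = [lookup.get(k, 0.0) for k in keys]
        condition_of[rep.sample_id] = rep.condition or rep.sample_id
        totals[rep.sample_id] = rep.total_reads
    index = pd.Index(list(keys), dtype=object, tupleize_cols=False,
                     name="clonotype")
    df = pd.DataFrame(data, index=index)
    return ConditionMatrix(frequencies=df, condition_of=condition_of,
                           total_reads=totals)


def fold_enrichment(cet: Cet, cond: ConditionMatrix, reference: str,
                    floor: Optional[float] = None,
                    average: str = "geometric") -> Dict[str, float]:
    """Per-condition average fold enrichment of a CET versus the reference.

    Per member: fold = condition frequency / max(reference frequency, floor);
    the CET average is the geometric mean of member folds (folds span orders
    of magnitude). ``floor`` defaults to 1 / total reference reads, the
    detection limit of the reference sample's depth.
    """
    if reference not in cond.conditions:
        raise ValueError(f"reference condition {reference!r} not present")
    ref_samples = cond.samples_for(reference)
    if floor is None:
        total = sum(cond.total_reads.get(s, 0) for s in ref_samples)
        floor = 1.0 / total if total > 0 else 1e-6
    keys = [k for k in cet.member_keys if k in cond.frequencies.index]
    if not keys:
        return {}
    ref_freq = cond.frequencies.loc[keys, ref_samples].mean(axis=1)
    out: Dict[str, float] = {}
    for condition in cond.conditions:
        cols = cond.samples_for(condition)
        freq = cond.frequencies.loc[keys, cols].mean(axis=1)
        folds = freq.to_numpy() / np.maximum(ref_freq.to_numpy(), floor)
        folds = np.maximum(folds, 1e-12)  # members absent everywhere
        if average == "geometric":
            out[condition] = float(np.exp(np.mean(np.log(folds))))
        elif average == "arithmetic":
            out[condition] = float(np.mean(folds))
        else:
            raise ValueError("average must be 'geometric' or 'arithmetic'")
    return out


def enriched_cets(cets: Sequence[Cet], cond: ConditionMatrix, reference: str,
                  cutoff: float = 100.0, min_members: int = 3,
                  floor: Optional[float] = None,
                  average: str = "geometric") -> List[Tuple[Cet, Dict[str, float]]]:
    """Display filter: CETs with >= min_members and >= cutoff average
    enrichment in any non-reference condition over the reference."""
    out = []
    for cet in cets:
        if cet.n_members < min_members:
            continue
        folds = fold_enrichment(cet, cond, reference, floor=floor,
                                average=average)
        if any(f >= cutoff for c, f in folds.items() if c != reference):
            out.append((cet, folds))
    return out


def query_deep(members: Sequence[Clonotype], deep: Repertoire) -> pd.DataFrame:
    """Exact nucleotide-level clonotype matches of CET members in a deep
    repertoire; unmatched members are reported with frequency 0."""
    lookup = {c.key: c for c in deep}
    rows = []
    for m in members:
        hit = lookup.get(m.key)
        rows.append(dict(v_call=m.v_call, j_call=m.j_call, cdr3_nt=m.cdr3_nt,
                         cdr3_aa=m.cdr3_aa, deep_sample=deep.sample_id,
                         found=hit is not None,
                         frequency=hit.frequency if hit else 0.0,
                         count=hit.count if hit else 0))
    return pd.DataFrame(rows, columns=["v_call", "j_call", "cdr3_nt", "cdr3_aa",
                                       "deep_sample", "found", "frequency",
                                       "count"])


def consensus_cdr3(members: Sequence[Clonotype], min_share: float = 0.5) -> str:
    """Modal-residue consensus over the CET's dominant CDR3 length;
    'x' marks columns where no residue reaches ``min_share``."""
    if not members:
        return ""
    lengths = [len(m.cdr3_aa) for m in members]
    modal = max(sorted(set(lengths)), key=lengths.count)
    seqs = [m.cdr3_aa for m in members if len(m.cdr3_aa) == modal]
    out = []
    for pos in range(modal):
        col = [s[pos] for s in seqs]
        best = max(sorted(set(col)), key=col.count)
        out.append(best if col.count(best) / len(col) >= min_share else "x")
    return "".join(out)
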