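"""Empirical significance of observed clusters against the recombination null.

Each observed cluster at a threshold is parameterised by its member count and
the geometric mean frequency of its members. Its empirical p-value is the
fraction of null trials that contain, at the same threshold, at least one
cluster at least as large (dominance mode, the default) — or exactly as large
(exact mode) — with a geometric mean frequency at least as high. A cluster is
a significant CET when p < alpha (default 0.01, i.e. fewer than 10
occurrences in 1000 trials). No multiple-testing correction is applied across
thresholds or clusters; cross-threshold redundancy is handled downstream by
master-list aggregation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

from .cluster import ClusterAssignment, ThresholdLadder
from .metric import TcrdistParams
from .nullmodel import NullTrial, geometric_mean
from .repertoire import Clonotype, ClonotypeKey, Repertoire

SIZE_MODES = ("at_least_size", "exact_size")


@dataclass(frozen=True)
class Cet:
    """A cluster of expanded TCRs at one threshold, with its empirical p-value."""

    cet_id: str
    threshold: int
    members: Tuple[Clonotype, ...]
    n_members: int
    geo_mean_freq: float
    p_value: Optional[float]
    n_exceed: int
    n_trials: int
    significant: bool
    sample_id: str = ""
    condition: str = ""
    size_mode: str = "at_least_size"

    @property
    def member_keys(self) -> Tuple[ClonotypeKey, ...]:
        return tuple(c.key for c in self.members)

    @property
    def chain(self) -> str:
        return self.members[0].chain

    def p_display(self) -> str:
        if self.p_value is None:
            return "NA"
        if self.n_exceed == 0 and self.n_trials > 0:
            return f"<{1 / self.n_trials:g}"
        return f"{self.p_value:g}"


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the CET pipeline, serialisable into run manifests."""

    shortlist_n: int = 1000
    ladder: ThresholdLadder = field(default_factory=ThresholdLadder)
    n_trials: int = 1000
    alpha: float = 0.01
    min_members: int = 2
    report_min_members: int = 3
    linkage: str = "complete"
    tcrdist: TcrdistParams = field(default_factory=TcrdistParams)
    size_mode: str = "at_least_size"
    null_mode: str = "replacement"
    enrichment_cutoff: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.shortlist_n < self.min_members:
            raise ValueError("shortlist_n must be >= min_members")
        if self.size_mode not in SIZE_MODES:
            raise ValueError(f"size_mode must be one of {SIZE_MODES}")

    def to_dict(self) -> Dict[str, object]:
        d = asdict(self)
        d["ladder"] = list(self.ladder.thresholds)
        return d

    @classmethod
    def from_dict(cls, d: Dict[str, object]) -> "PipelineConfig":
        d = dict(d)
        if "ladder" in d and not isinstance(d["ladder"], ThresholdLadder):
            d["ladder"] = ThresholdLadder(tuple(int(t) for t in d["ladder"]))
        if "tcrdist" in d and isinstance(d["tcrdist"], dict):
            d["tcrdist"] = TcrdistParams(**d["tcrdist"])
        return cls(**d)


def cluster_params(freqs: Sequence[float]) -> Tuple[int, float]:
    """(member count, geometric mean frequency) of one cluster."""
    return len(freqs), geometric_mean(freqs)


def empirical_p(obs: Tuple[int, float], threshold: int,
                trials: Sequence[NullTrial],
                mode: str = "at_least_size") -> Tuple[float, int]:
    """Empirical p-value of an observed (size, gmean) pair at a threshold.

    A trial counts toward n_exceed when it contains >= 1 cluster at the
    queried threshold whose size dominates (>=, or == in exact mode) the
    observed size and whose geometric mean frequency is >= the observed one.
    """
    if mode not in SIZE_MODES:
        raise ValueError(f"mode must be one of {SIZE_MODES}")
    n_obs, g_obs = obs
    n_exceed = 0
    for trial in trials:
        if threshold not in trial.by_threshold:
            raise ValueError(f"threshold {threshold} absent from trial "
                             f"{trial.trial_id}")
        for size, gmean in trial.by_threshold[threshold]:
            size_ok = size >= n_obs if mode == "at_least_size" else size == n_obs
            if size_ok and gmean >= g_obs:
                n_exceed += 1
                break
    return n_exceed / len(trials), n_exceed


def call_cets(assignments: Sequence[ClusterAssignment], shortlist: Repertoire,
              trials: Sequence[NullTrial], config: PipelineConfig) -> List[Cet]:
    """Score every >= min_members cluster at every ladder threshold."""
    freqs = shortlist.frequencies
    clons = shortlist.clonotypes
    n_trials = len(trials)
    cets: List[Cet] = []
    for assign in assignments:
        t = int(assign.threshold)
        idx = 0
        for members in assign.clusters:
            if len(members) < config.min_members:
                continue
            member_clons = tuple(clons[m] for m in members)
            n, gmean = cluster_params(freqs[list(members)])
            p, n_exceed = empirical_p((n, gmean), t, trials, config.size_mode)
            cets.append(Cet(
                cet_id=f"{shortlist.sample_id or 'sample'}:t{t}:c{idx}",
                threshold=t, members=member_clons, n_members=n,
                geo_mean_freq=gmean, p_value=p, n_exceed=n_exceed,
                n_trials=n_trials, significant=p < config.alpha,
                sample_id=shortlist.sample_id, condition=shortlist.condition,
                size_mode=config.size_mode))
            idx += 1
    return cets


def significant_cets(cets: Sequence[Cet],
                     min_members: Optional[int] = None) -> List[Cet]:
    out = [c for c in cets if c.significant]
    if min_members is not None:
        out = [c for c in out if c.n_members >= min_members]
    return out
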