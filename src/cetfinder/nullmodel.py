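"""Element-recombination null model for cluster significance.

Each productively rearranged TCR junction is decomposed into 14 recombination
elements as exported by germline aligners: the germline V/D/J calls, the
3'V / 5'D / 3'D / 5'J trim counts, P-segment nucleotides, and the
non-templated junction inserts (V-D and D-J for β chains, the single V-J
insert for α chains). Random TCRs are produced by resampling each element
independently from a background pool built from a large reference repertoire
— this destroys any V-junction-J linkage carried by real receptors while
preserving the marginal usage of every element — and reassembling the CDR3
from germline sequence plus the drawn inserts. Non-productive assemblies
(out of frame, stop codon, missing the conserved leading cysteine) are
rejected and redrawn.

A null *trial* is a repertoire of n such TCRs carrying exactly the observed
shortlist's frequency multiset (assigned by a uniformly random permutation),
clustered with the same metric, linkage and threshold ladder as the observed
analysis and reduced to per-threshold (cluster size, geometric mean
frequency) pairs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .cluster import ThresholdLadder, sweep
from .germline import GermlineCdrTable, GermlineNtTable
from .metric import TcrdistParams, pairwise_matrix
from .repertoire import Clonotype, Repertoire, translate

#: canonical order of the 14 junction elements
ELEMENT_SLOTS = (
    "bestVHit", "V3dels_or_Ps", "nSeqVPSegment", "nSeqVDJunction",
    "nSeqDLeftPSegment", "D5dels_or_Ps", "bestDHit", "D3dels_or_Ps",
    "nSeqDRightPSegment", "nSeqDJJunction", "nSeqJPSegment", "J5dels_or_Ps",
    "bestJHit", "nSeqVJJunction",
)

_INT_SLOTS = {"V3dels_or_Ps", "D5dels_or_Ps", "D3dels_or_Ps", "J5dels_or_Ps"}
_D_SLOTS = ("nSeqDLeftPSegment", "D5dels_or_Ps", "bestDHit", "D3dels_or_Ps",
            "nSeqDRightPSegment", "nSeqDJJunction", "nSeqVDJunction")


@dataclass(frozen=True)
class TcrElements:
    """One junction's 14 recombination elements (attribute names mirror the
    aligner export columns; trim slots are non-negative deletion counts,
    P nucleotides live in the nSeq*PSegment slots)."""

    bestVHit: str
    V3dels_or_Ps: int
    nSeqVPSegment: str
    nSeqVDJunction: str
    nSeqDLeftPSegment: str
    D5dels_or_Ps: int
    bestDHit: str
    D3dels_or_Ps: int
    nSeqDRightPSegment: str
    nSeqDJJunction: str
    nSeqJPSegment: str
    J5dels_or_Ps: int
    bestJHit: str
    nSeqVJJunction: str

    def as_dict(self) -> Dict[str, object]:
        return {s: getattr(self, s) for s in ELEMENT_SLOTS}

    def validate_chain(self, chain: str) -> None:
        d_used = (self.bestDHit or self.nSeqVDJunction or self.nSeqDJJunction
                  or self.nSeqDLeftPSegment or self.nSeqDRightPSegment)
        if chain == "alpha" and d_used:
            raise ValueError("alpha-chain elements must leave D slots empty")
        if chain == "beta" and self.nSeqVJJunction:
            raise ValueError("beta-chain elements must leave nSeqVJJunction empty")


def decompose(row: Mapping[str, object]) -> TcrElements:
    """Build TcrElements from a table row carrying the 14 element columns."""
    values = {}
    for slot in ELEMENT_SLOTS:
        if slot not in row:
            raise KeyError(f"missing junction-element column {slot!r}")
        v = row[slot]
        if slot in _INT_SLOTS:
            values[slot] = int(v) if v not in ("", None) and v == v else 0
        else:
            values[slot] = "" if v is None or v != v else str(v)
    return TcrElements(**values)


def reassemble(el: TcrElements, nt_table: GermlineNtTable, chain: str) -> str:
    """CDR3 nucleotide sequence implied by a set of junction elements."""
    v = nt_table.v_prefix(el.bestVHit, chain)
    if el.V3dels_or_Ps > len(v):
        raise ValueError("V 3' deletion exceeds germline CDR3 prefix")
    parts = [v[:len(v) - el.V3dels_or_Ps] if el.V3dels_or_Ps else v,
             el.nSeqVPSegment]
    if chain == "beta":
        d = nt_table.d(el.bestDHit) if el.bestDHit else ""
        if el.D5dels_or_Ps + el.D3dels_or_Ps > len(d):
            d_trimmed = ""
        else:
            d_trimmed = d[el.D5dels_or_Ps:len(d) - el.D3dels_or_Ps] \
                if el.D3dels_or_Ps else d[el.D5dels_or_Ps:]
        parts += [el.nSeqVDJunction, el.nSeqDLeftPSegment, d_trimmed,
                  el.nSeqDRightPSegment, el.nSeqDJJunction]
    else:
        parts.append(el.nSeqVJJunction)
    j = nt_table.j_suffix(el.bestJHit, chain)
    if el.J5dels_or_Ps > len(j):
        raise ValueError("J 5' deletion exceeds germline CDR3 suffix")
    parts += [el.nSeqJPSegment, j[el.J5dels_or_Ps:]]
    return "".join(parts)


@dataclass
class ElementPools:
    """Per-slot multisets of observed element values for one chain."""

    chain: str
    pools: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        slots = self.active_slots(self.chain)
        for slot in slots:
            pool = self.pools.get(slot)
            if pool is None or len(pool) == 0:
                raise ValueError(f"empty element pool for slot {slot!r} ({self.chain})")

    @staticmethod
    def active_slots(chain: str) -> Tuple[str, ...]:
        if chain == "alpha":
            return tuple(s for s in ELEMENT_SLOTS if s not in _D_SLOTS)
        return tuple(s for s in ELEMENT_SLOTS if s != "nSeqVJJunction")

    @classmethod
    def from_repertoire(cls, rep: Repertoire, chain: Optional[str] = None) -> "ElementPools":
        chain = chain or rep.chain
        slots = cls.active_slots(chain)
        columns: Dict[str, list] = {s: [] for s in slots}
        for c in rep:
            if c.elements is None:
                raise ValueError(
                    f"clonotype {c.key} has no junction elements; background "
                    f"tables must include the element columns")
            for s in slots:
                columns[s].append(getattr(c.elements, s))
        pools = {s: np.array(v, dtype=(np.int64 if s in _INT_SLOTS else object))
                 for s, v in columns.items()}
        return cls(chain=chain, pools=pools)


@dataclass(frozen=True)
class NullTrial:
    """Per-threshold (cluster_size, geo_mean_freq) pairs from one random trial."""

    trial_id: int
    by_threshold: Dict[int, Tuple[Tuple[int, float], ...]]


class GenerationError(RuntimeError):
    pass


def _assemble_elements(draw: Dict[str, object], chain: str) -> TcrElements:
    full = {s: (0 if s in _INT_SLOTS else "") for s in ELEMENT_SLOTS}
    full.update(draw)
    return TcrElements(**full)


def _productive_cdr3(nt: str) -> Optional[str]:
    if not nt or len(nt) % 3:
        return None
    aa = translate(nt)
    if "*" in aa or not aa.startswith("C"):
        return None
    return aa


def generate_random_tcr(pools: ElementPools, chain: str, rng: np.random.Generator,
                        nt_table: GermlineNtTable, max_attempts: int = 1000,
                        sample_id: str = "null") -> Clonotype:
    """One productive random TCR with every slot drawn uniformly from its pool."""
    slots = ElementPools.active_slots(chain)
    for _ in range(max_attempts):
        draw = {s: pools.pools[s][rng.integers(len(pools.pools[s]))] for s in slots}
        draw = {s: (int(v) if s in _INT_SLOTS else str(v)) for s, v in draw.items()}
        el = _assemble_elements(draw, chain)
        try:
            nt = reassemble(el, nt_table, chain)
        except ValueError:
            continue
        aa = _productive_cdr3(nt)
        if aa is None:
            continue
        return Clonotype(chain=chain, v_call=el.bestVHit, j_call=el.bestJHit,
                         d_call=el.bestDHit or None, cdr3_nt=nt, cdr3_aa=aa,
                         count=0, frequency=0.0, sample_id=sample_id, elements=el)
    raise GenerationError(
        f"no productive assembly within {max_attempts} attempts from pools for "
        f"chain {chain!r}; check germline reference and element pools")


def _batched_random_tcrs(pools: ElementPools, chain: str, n: int,
                         rng: np.random.Generator, nt_table: GermlineNtTable,
                         max_attempts: int, mode: str) -> List[Clonotype]:
    """Draw n productive TCRs; slot indices are drawn in batches for speed."""
    slots = ElementPools.active_slots(chain)
    out: List[Clonotype] = []
    attempts = 0
    budget = max_attempts * n
    if mode == "permutation":
        # permute each slot column without replacement; rejected assemblies
        # consume their drawn values (documented approximation); refill by
        # reshuffling when a column is exhausted
        iters = {s: iter(rng.permutation(pools.pools[s])) for s in slots}

        def next_draw():
            d = {}
            for s in slots:
                try:
                    v = next(iters[s])
                except StopIteration:
                    iters[s] = iter(rng.permutation(pools.pools[s]))
                    v = next(iters[s])
                d[s] = int(v) if s in _INT_SLOTS else str(v)
            return d

        draws = None
    else:
        draws = None

    batch_pos = 0
    batch_size = 0
    while len(out) < n:
        if attempts >= budget:
            raise GenerationError(
                f"exceeded {max_attempts} average attempts per TCR for chain "
                f"{chain!r}; check germline reference and element pools")
        if mode == "permutation":
            draw = next_draw()
        else:
            if batch_pos >= batch_size:
                batch_size = max(4 * (n - len(out)), 64)
                draws = {s: pools.pools[s][rng.integers(len(pools.pools[s]),
                                                        size=batch_size)]
                         for s in slots}
                batch_pos = 0
            draw = {s: draws[s][batch_pos] for s in slots}
            draw = {s: (int(v) if s in _INT_SLOTS else str(v))
                    for s, v in draw.items()}
            batch_pos += 1
        attempts += 1
        el = _assemble_elements(draw, chain)
        try:
            nt = reassemble(el, nt_table, chain)
        except ValueError:
            continue
        aa = _productive_cdr3(nt)
        if aa is None:
            continue
        out.append(Clonotype(chain=chain, v_call=el.bestVHit, j_call=el.bestJHit,
                             d_call=el.bestDHit or None, cdr3_nt=nt, cdr3_aa=aa,
                             count=0, frequency=0.0, sample_id="null", elements=el))
    return out


def generate_trial(pools: ElementPools, observed_freqs: Sequence[float],
                   n: int, rng: np.random.Generator, nt_table: GermlineNtTable,
                   chain: Optional[str] = None, mode: str = "replacement",
                   max_attempts: int = 1000, sample_id: str = "null") -> Repertoire:
    """Random repertoire of n TCRs carrying exactly ``observed_freqs``.

    Frequencies are assigned to the generated members by a uniformly random
    permutation; the trial's frequency multiset equals the observed one.
    """
    if len(observed_freqs) != n:
        raise ValueError(f"|observed_freqs| = {len(observed_freqs)} != n = {n}")
    if mode not in ("replacement", "permutation"):
        raise ValueError("mode must be 'replacement' or 'permutation'")
    chain = chain or pools.chain
    clons = _batched_random_tcrs(pools, chain, n, rng, nt_table, max_attempts, mode)
    freqs = np.asarray(observed_freqs, dtype=float)
    perm = rng.permutation(n)
    assigned = [c.with_frequency(float(freqs[perm[i]])) for i, c in enumerate(clons)]
    for i, c in enumerate(assigned):
        assigned[i] = Clonotype(chain=c.chain, v_call=c.v_call, j_call=c.j_call,
                                d_call=c.d_call, cdr3_nt=c.cdr3_nt, cdr3_aa=c.cdr3_aa,
                                count=c.count, frequency=c.frequency,
                                sample_id=sample_id, elements=c.elements)
    return Repertoire.build(assigned, sample_id=sample_id, renormalize=False)


def geometric_mean(freqs: Sequence[float]) -> float:
    arr = np.asarray(freqs, dtype=float)
    if (arr <= 0).any():
        raise ValueError("frequencies must be strictly positive")
    return float(np.exp(np.mean(np.log(arr))))


def summarize_trial(trial: Repertoire, trial_id: int, table: GermlineCdrTable,
                    params: TcrdistParams, ladder: ThresholdLadder,
                    linkage: str, min_members: int = 2) -> NullTrial:
    """Cluster one trial and reduce it to per-threshold parameter pairs."""
    matrix = pairwise_matrix(trial, table, params)
    assignments = sweep(matrix, ladder, linkage)
    freqs = trial.frequencies
    by_threshold: Dict[int, Tuple[Tuple[int, float], ...]] = {}
    for assign in assignments:
        pairs = []
        for members in assign.clusters:
            if len(members) >= min_members:
                gmean = geometric_mean(freqs[list(members)])
                pairs.append((len(members), gmean))
        by_threshold[int(assign.threshold)] = tuple(pairs)
    return NullTrial(trial_id=trial_id, by_threshold=by_threshold)


def run_null(pools: ElementPools, observed_freqs: Sequence[float],
             ladder: ThresholdLadder, n_trials: int, seed,
             nt_table: GermlineNtTable, table: GermlineCdrTable,
             params: TcrdistParams = TcrdistParams(), linkage: str = "complete",
             chain: Optional[str] = None, mode: str = "replacement",
             min_members: int = 2) -> List[NullTrial]:
    """Generate, cluster and summarise ``n_trials`` independent null trials."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    chain = chain or pools.chain
    n = len(observed_freqs)
    seqs = np.random.SeedSequence(seed).spawn(n_trials)
    trials = []
    for t, ss in enumerate(seqs):
        rng = np.random.default_rng(ss)
        trial = generate_trial(pools, observed_freqs, n, rng, nt_table,
                               chain=chain, mode=mode, sample_id=f"null-{t}")
        trials.append(summarize_trial(trial, t, table, params, ladder,
                                      linkage, min_members=min_members))
    return trials
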