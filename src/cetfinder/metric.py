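"""The v1 TCRdist similarity metric between TCR clonotypes.

TCRdist scores amino-acid similarity over the four CDR loops most likely to
contact peptide:MHC — CDR1, CDR2, the "CDR2.5" loop, and the CDR3. The three
germline loops are looked up from the V gene; the CDR3 is the IMGT junction
trimmed of its conserved anchors (3 N-terminal, 2 C-terminal residues).
Per position the cost is ``min(cap, cap - S(a, b))`` clamped at 0, with S the
BLOSUM62 score and cap 4 (so identities cost 0 and any strongly dissimilar
pair saturates at 4). Loops of unequal length are aligned by inserting one
contiguous gap block into the shorter loop at the position minimising total
cost (leftmost on ties), each gap position costing 4. Loop scores are summed
with the CDR3 triple-weighted, giving an integer distance: 0 for identical
CDR sequences, typically >100 for unrelated receptors.

The scalar functions here are the reference implementation; ``pairwise_matrix``
dispatches to a numba kernel that is integer-exact against them.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .germline import GermlineCdrTable
from .repertoire import Clonotype, ClonotypeKey, Repertoire

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: Dict[str, int] = {a: i for i, a in enumerate(AA_ALPHABET)}


@dataclass(frozen=True)
class TcrdistParams:
    """Tunable constants of the metric (defaults follow the v1 definition)."""

    mismatch_cap: int = 4
    gap_penalty: int = 4
    cdr3_weight: int = 3
    other_cdr_weight: int = 1
    cdr3_trim_nterm: int = 3
    cdr3_trim_cterm: int = 2
    substitution_matrix: str = "BLOSUM62"
    on_nonstandard: str = "raise"  # or "max": score any non-standard residue at cap

    def __post_init__(self) -> None:
        for name in ("mismatch_cap", "gap_penalty", "cdr3_weight",
                     "other_cdr_weight", "cdr3_trim_nterm", "cdr3_trim_cterm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.on_nonstandard not in ("raise", "max"):
            raise ValueError("on_nonstandard must be 'raise' or 'max'")


@functools.lru_cache(maxsize=8)
def _cost_table(matrix_name: str, cap: int) -> np.ndarray:
    """21x21 per-position cost table; index 20 is the non-standard bucket."""
    from Bio.Align import substitution_matrices

    sub = substitution_matrices.load(matrix_name)
    table = np.full((21, 21), cap, dtype=np.int64)
    for a, i in AA_INDEX.items():
        for b, j in AA_INDEX.items():
            s = int(sub[a, b])
            table[i, j] = min(cap, max(0, cap - s))
    return table


def _encode(s: str) -> np.ndarray:
    return np.array([AA_INDEX.get(ch, 20) for ch in s], dtype=np.int64)


def aa_distance(a: str, b: str, params: TcrdistParams = TcrdistParams()) -> int:
    """Per-position substitution cost between two residues."""
    if a not in AA_INDEX or b not in AA_INDEX:
        if params.on_nonstandard == "raise":
            bad = a if a not in AA_INDEX else b
            raise ValueError(f"non-standard amino acid {bad!r}")
        return params.mismatch_cap
    table = _cost_table(params.substitution_matrix, params.mismatch_cap)
    return int(table[AA_INDEX[a], AA_INDEX[b]])


def cdr_distance(s1: str, s2: str, weight: int = 1,
                 params: TcrdistParams = TcrdistParams()) -> int:
    """Weighted distance between two CDR loops.

    Equal-length loops are scored position-wise. For unequal lengths a single
    contiguous gap block is inserted into the shorter loop at the position
    minimising total cost (leftmost on ties); each gap position costs
    ``gap_penalty``.
    """
    if len(s1) > len(s2):
        s1, s2 = s2, s1
    short, long = s1, s2
    ls, ll = len(short), len(long)
    dlen = ll - ls
    if params.on_nonstandard == "raise":
        for ch in short + long:
            if ch not in AA_INDEX:
                raise ValueError(f"non-standard amino acid {ch!r}")
    table = _cost_table(params.substitution_matrix, params.mismatch_cap)
    a, b = _encode(short), _encode(long)
    if dlen == 0:
        subs = int(table[a, b].sum()) if ls else 0
        return weight * subs
    best = None
    for g in range(ls + 1):
        cost = 0
        for p in range(g):
            cost += int(table[a[p], b[p]])
        for p in range(g, ls):
            cost += int(table[a[p], b[p + dlen]])
        if best is None or cost < best:
            best = cost
    return weight * (best + dlen * params.gap_penalty)


def trim_cdr3(junction_aa: str, params: TcrdistParams = TcrdistParams()) -> str:
    """IMGT junction minus its conserved anchors (min length 0)."""
    start = params.cdr3_trim_nterm
    stop = len(junction_aa) - params.cdr3_trim_cterm
    return junction_aa[start:stop] if stop > start else ""


@dataclass(frozen=True)
class CdrProfile:
    """The four scored loops of one receptor chain."""

    cdr1: str
    cdr2: str
    cdr2_5: str
    cdr3_trimmed: str

    @classmethod
    def from_clonotype(cls, c: Clonotype, table: GermlineCdrTable,
                       params: TcrdistParams = TcrdistParams()) -> "CdrProfile":
        cdr1, cdr2, cdr2_5 = table.get(c.v_call, c.chain)
        return cls(cdr1, cdr2, cdr2_5, trim_cdr3(c.cdr3_aa, params))


def tcrdist(c1: Clonotype, c2: Clonotype, table: GermlineCdrTable,
            params: TcrdistParams = TcrdistParams()) -> int:
    """Scalar TCRdist between two same-chain clonotypes."""
    if c1.chain != c2.chain:
        raise ValueError(f"chain mismatch: {c1.chain} vs {c2.chain}")
    p1 = CdrProfile.from_clonotype(c1, table, params)
    p2 = CdrProfile.from_clonotype(c2, table, params)
    w = params.other_cdr_weight
    return (cdr_distance(p1.cdr1, p2.cdr1, w, params)
            + cdr_distance(p1.cdr2, p2.cdr2, w, params)
            + cdr_distance(p1.cdr2_5, p2.cdr2_5, w, params)
            + cdr_distance(p1.cdr3_trimmed, p2.cdr3_trimmed,
                           params.cdr3_weight, params))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric integer pairwise distances over an ordered clonotype list."""

    labels: Tuple[ClonotypeKey, ...]
    values: np.ndarray = field(compare=False)

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape does not match labels")
        if (v < 0).any():
            raise ValueError("negative distances")
        if (np.diag(v) != 0).any():
            raise ValueError("non-zero diagonal")
        if not (v == v.T).all():
            raise ValueError("matrix is not symmetric")

    def __len__(self) -> int:
        return len(self.labels)


@functools.lru_cache(maxsize=64)
def _germline_component(loop_triples: Tuple[Tuple[str, str, str], ...],
                        params: TcrdistParams) -> np.ndarray:
    """Distance contribution of the three germline loops per V-profile pair."""
    n = len(loop_triples)
    out = np.zeros((n, n), dtype=np.int64)
    w = params.other_cdr_weight
    for i in range(n):
        for j in range(i + 1, n):
            a, b = loop_triples[i], loop_triples[j]
            d = sum(cdr_distance(a[k], b[k], w, params) for k in range(3))
            out[i, j] = out[j, i] = d
    return out


def pairwise_matrix(shortlist: Repertoire, table: GermlineCdrTable,
                    params: TcrdistParams = TcrdistParams()) -> DistanceMatrix:
    """All-pairs TCRdist over a single-chain shortlist (numba-accelerated)."""
    if len(shortlist) == 0:
        raise ValueError("empty shortlist")
    chain = shortlist.chain  # raises on mixed chains
    clons = shortlist.clonotypes

    # unique germline loop profiles -> small precomputed component matrix
    triples = [table.get(c.v_call, chain) for c in clons]
    uniq = sorted(set(triples))
    tindex = {t: i for i, t in enumerate(uniq)}
    vidx = np.array([tindex[t] for t in triples], dtype=np.int64)
    vcomp = _germline_component(tuple(uniq), params)

    cdr3s = [trim_cdr3(c.cdr3_aa, params) for c in clons]
    if params.on_nonstandard == "raise":
        for s in cdr3s:
            for ch in s:
                if ch not in AA_INDEX:
                    raise ValueError(f"non-standard amino acid {ch!r} in CDR3")
    lens = np.array([len(s) for s in cdr3s], dtype=np.int64)
    lmax = int(lens.max()) if len(lens) else 0
    seqs = np.zeros((len(clons), max(lmax, 1)), dtype=np.int64)
    for i, s in enumerate(cdr3s):
        if s:
            seqs[i, :len(s)] = _encode(s)

    cost = _cost_table(params.substitution_matrix, params.mismatch_cap)
    from ._pairwise import pairwise_kernel

    values = pairwise_kernel(seqs, lens, vidx, vcomp, cost,
                             np.int64(params.gap_penalty),
                             np.int64(params.cdr3_weight))
    return DistanceMatrix(labels=shortlist.keys(), values=values)
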