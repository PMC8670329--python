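"""Clonotype and repertoire containers.

A clonotype is a unique rearranged TCR chain, keyed by its V segment, J
segment and CDR3 nucleotide sequence; a repertoire is the set of clonotypes
detected in one sample, carrying read counts and within-sample frequencies.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Iterator, Optional, Tuple

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .nullmodel import TcrElements

CHAINS = ("alpha", "beta")

#: codon -> amino acid, '*' for stop
CODON_TABLE = {}
_BASES = "TCAG"
_AA64 = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            CODON_TABLE[_b1 + _b2 + _b3] = _AA64[16 * _i + 4 * _j + _k]

ClonotypeKey = Tuple[str, str, str]


def translate(nt: str) -> str:
    """Translate an in-frame nucleotide string; raises on partial codons."""
    if len(nt) % 3:
        raise ValueError(f"nucleotide length {len(nt)} is not a multiple of 3")
    return "".join(CODON_TABLE[nt[i:i + 3]] for i in range(0, len(nt), 3))


def strip_allele(call: str) -> str:
    """Drop the IMGT allele suffix, e.g. 'TRBV19*01' -> 'TRBV19'."""
    return call.split("*", 1)[0]


def chain_of_call(call: str) -> Optional[str]:
    gene = strip_allele(call)
    if gene.startswith("TRA"):
        return "alpha"
    if gene.startswith("TRB"):
        return "beta"
    return None


@dataclass(frozen=True)
class Clonotype:
    chain: str
    v_call: str
    j_call: str
    cdr3_nt: str
    cdr3_aa: str
    count: int = 0
    frequency: float = 0.0
    d_call: Optional[str] = None
    sample_id: str = ""
    elements: Optional["TcrElements"] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise ValueError(f"unknown chain {self.chain!r}")
        if self.count < 0:
            raise ValueError("count must be non-negative")

    @property
    def key(self) -> ClonotypeKey:
        return (self.v_call, self.j_call, self.cdr3_nt)

    @property
    def v_gene(self) -> str:
        return strip_allele(self.v_call)

    @property
    def j_gene(self) -> str:
        return strip_allele(self.j_call)

    def is_productive(self) -> bool:
        """In-frame, stop-free CDR3 whose translation matches cdr3_aa."""
        if len(self.cdr3_nt) != 3 * len(self.cdr3_aa):
            return False
        return "*" not in self.cdr3_aa

    def with_frequency(self, frequency: float, count: Optional[int] = None) -> "Clonotype":
        return replace(self, frequency=frequency,
                       count=self.count if count is None else count)


def _sort_key(c: Clonotype):
    # descending frequency; deterministic lexicographic tie-break
    return (-c.frequency, c.cdr3_nt, c.v_call, c.j_call)


@dataclass
class Repertoire:
    """Ordered clonotype collection for one sample.

    Clonotypes are kept sorted by descending frequency with a deterministic
    lexicographic tie-break, so shortlists and downstream cluster ids are
    stable across runs and platforms.
    """
    sample_id: str
    clonotypes: Tuple[Clonotype, ...]
    condition: str = ""
    total_reads: int = 0

    @classmethod
    def build(cls, clonotypes: Iterable[Clonotype], sample_id: str = "",
              condition: str = "", total_reads: Optional[int] = None,
              renormalize: bool = True) -> "Repertoire":
        clons = list(clonotypes)
        total = sum(c.count for c in clons) if total_reads is None else total_reads
        if renormalize and total > 0:
            clons = [c.with_frequency(c.count / total) for c in clons]
        clons.sort(key=_sort_key)
        return cls(sample_id=sample_id, clonotypes=tuple(clons),
                   condition=condition, total_reads=total)

    def __len__(self) -> int:
        return len(self.clonotypes)

    def __iter__(self) -> Iterator[Clonotype]:
        return iter(self.clonotypes)

    def __getitem__(self, i: int) -> Clonotype:
        return self.clonotypes[i]

    @property
    def chain(self) -> str:
        chains = {c.chain for c in self.clonotypes}
        if len(chains) != 1:
            raise ValueError(f"repertoire is not single-chain: {sorted(chains)}")
        return next(iter(chains))

    @property
    def frequencies(self):
        import numpy as np

        return np.array([c.frequency for c in self.clonotypes], dtype=float)

    def keys(self) -> Tuple[ClonotypeKey, ...]:
        return tuple(c.key for c in self.clonotypes)
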