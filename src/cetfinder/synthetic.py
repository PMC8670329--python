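"""Self-contained synthetic repertoires for testing and benchmarking.

Emulates the statistical structure the CET analysis assumes: realistic V/J
usage (Zipf-skewed over the bundled synthetic germline set), CDR3 length
variation from random junction inserts and trims, a heavy-tailed clone-size
distribution (discrete power law, exponent ~2), strong culture-to-culture
clonotype turnover, and optional spiked families of homologous, expanded
clonotypes with a truth table for recovery metrics. No claim of biological
realism beyond these marginals is made.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .germline import GermlineNtTable, synthetic_nt_table
from .metric import TcrdistParams, trim_cdr3
from .nullmodel import ElementPools, TcrElements, _productive_cdr3, reassemble
from .repertoire import Clonotype, Repertoire, translate

_NT = "ACGT"

#: codon used when back-translating a substituted residue
_AA_TO_CODON = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAG", "R": "CGT", "S": "AGC", "T": "ACC", "V": "GTG",
    "W": "TGG", "Y": "TAC",
}
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SpikeSpec:
    """Spiked homologous expanded families (models antigen-driven expansion)."""

    n_families: int = 5
    members_per_family: int = 6
    cdr3_divergence: int = 2
    expansion_fold: float = 100.0
    chain: str = "beta"

    def __post_init__(self) -> None:
        if self.members_per_family < 3:
            raise ValueError("members_per_family must be >= 3 to be reportable")
        if self.cdr3_divergence < 0:
            raise ValueError("cdr3_divergence must be >= 0")


def _zipf_weights(k: int, s: float = 1.2) -> np.ndarray:
    w = 1.0 / np.arange(1, k + 1) ** s
    return w / w.sum()


def _power_law_counts(n: int, rng: np.random.Generator, exponent: float = 2.0,
                      cap: int = 10_000) -> np.ndarray:
    """Discrete power-law clone sizes, truncated at 1 read and capped."""
    u = rng.random(n)
    counts = np.floor(u ** (-1.0 / (exponent - 1.0))).astype(np.int64)
    return np.clip(counts, 1, cap)


def _random_insert(rng: np.random.Generator, max_len: int = 8) -> str:
    k = int(rng.integers(0, max_len + 1))
    return "".join(_NT[i] for i in rng.integers(0, 4, size=k))


def _random_elements(chain: str, nt_table: GermlineNtTable,
                     rng: np.random.Generator) -> TcrElements:
    v_genes = nt_table.v_genes(chain)
    j_genes = nt_table.j_genes(chain)
    vw = _zipf_weights(len(v_genes))
    jw = _zipf_weights(len(j_genes))
    v = v_genes[rng.choice(len(v_genes), p=vw)]
    j = j_genes[rng.choice(len(j_genes), p=jw)]
    base = dict(bestVHit=v, V3dels_or_Ps=int(rng.integers(0, 4)),
                nSeqVPSegment="", nSeqVDJunction="", nSeqDLeftPSegment="",
                D5dels_or_Ps=0, bestDHit="", D3dels_or_Ps=0,
                nSeqDRightPSegment="", nSeqDJJunction="", nSeqJPSegment="",
                J5dels_or_Ps=int(rng.integers(0, 4)), bestJHit=j,
                nSeqVJJunction="")
    if chain == "beta":
        d_genes = sorted(nt_table.d_seg)
        d = d_genes[int(rng.integers(len(d_genes)))]
        base.update(bestDHit=d,
                    D5dels_or_Ps=int(rng.integers(0, 4)),
                    D3dels_or_Ps=int(rng.integers(0, 4)),
                    nSeqVDJunction=_random_insert(rng),
                    nSeqDJJunction=_random_insert(rng))
    else:
        base.update(nSeqVJJunction=_random_insert(rng, max_len=10))
    return TcrElements(**base)


def make_background(n: int, chain: str = "beta",
                    seed: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None,
                    nt_table: Optional[GermlineNtTable] = None,
                    exponent: float = 2.0,
                    sample_id: str = "background",
                    max_attempts: int = 1000) -> Tuple[Repertoire, ElementPools]:
    """n productive random clonotypes plus the element pools they define."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    nt_table = nt_table or synthetic_nt_table()
    clons: List[Clonotype] = []
    seen = set()
    attempts = 0
    while len(clons) < n:
        attempts += 1
        if attempts > max_attempts * n:
            raise RuntimeError("background generation failed to converge")
        el = _random_elements(chain, nt_table, rng)
        try:
            nt = reassemble(el, nt_table, chain)
        except ValueError:
            continue
        aa = _productive_cdr3(nt)
        if aa is None:
            continue
        key = (el.bestVHit, el.bestJHit, nt)
        if key in seen:
            continue
        seen.add(key)
        clons.append(Clonotype(chain=chain, v_call=el.bestVHit,
                               j_call=el.bestJHit, d_call=el.bestDHit or None,
                               cdr3_nt=nt, cdr3_aa=aa, count=0, frequency=0.0,
                               sample_id=sample_id, elements=el))
    counts = _power_law_counts(n, rng, exponent=exponent)
    clons = [c.with_frequency(0.0, count=int(k)) for c, k in zip(clons, counts)]
    rep = Repertoire.build(clons, sample_id=sample_id)
    pools = ElementPools.from_repertoire(rep, chain=chain)
    return rep, pools


def _mutate_cdr3(cdr3_nt: str, positions: List[int], rng: np.random.Generator,
                 params: TcrdistParams) -> Tuple[str, str]:
    """Substitute the trimmed-CDR3 residues at ``positions`` (codon-level)."""
    aa = translate(cdr3_nt)
    codons = [cdr3_nt[i:i + 3] for i in range(0, len(cdr3_nt), 3)]
    offset = params.cdr3_trim_nterm
    for pos in positions:
        aa_pos = offset + pos
        current = aa[aa_pos]
        choices = [a for a in _AA20 if a != current]
        new = choices[int(rng.integers(len(choices)))]
        codons[aa_pos] = _AA_TO_CODON[new]
    nt = "".join(codons)
    return nt, translate(nt)


def spike_families(rep: Repertoire, spec: SpikeSpec,
                   seed: Optional[int] = None,
                   rng: Optional[np.random.Generator] = None,
                   nt_table: Optional[GermlineNtTable] = None,
                   params: TcrdistParams = TcrdistParams(),
                   ) -> Tuple[Repertoire, pd.DataFrame]:
    """Add homologous expanded families to a repertoire.

    Each family shares one V/J pair and varies only at a fixed set of
    ``cdr3_divergence`` trimmed-CDR3 positions, so within-family pairwise
    TCRdist is bounded by divergence * mismatch_cap * cdr3_weight by
    construction. Member counts are expansion_fold times the median
    background count; the combined repertoire is renormalised.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    nt_table = nt_table or synthetic_nt_table()
    chain = spec.chain
    median_count = float(np.median([c.count for c in rep])) or 1.0
    spike_count = max(1, int(round(spec.expansion_fold * median_count)))

    spiked: List[Clonotype] = []
    truth_rows = []
    existing = {c.key for c in rep}
    for fam in range(spec.n_families):
        # a family seed: one productive random clonotype with a CDR3 long
        # enough to host the divergence positions
        for _ in range(1000):
            el = _random_elements(chain, nt_table, rng)
            try:
                nt = reassemble(el, nt_table, chain)
            except ValueError:
                continue
            aa = _productive_cdr3(nt)
            if aa is None:
                continue
            trimmed = trim_cdr3(aa, params)
            if len(trimmed) >= max(spec.cdr3_divergence, 4):
                break
        else:
            raise RuntimeError("could not draw a family seed clonotype")
        positions = sorted(rng.choice(len(trimmed), size=spec.cdr3_divergence,
                                      replace=False).tolist()) \
            if spec.cdr3_divergence else []
        family_id = f"family{fam}"
        members = [(nt, aa)]
        member_keys = {(el.bestVHit, el.bestJHit, nt)}
        guard = 0
        while len(members) < spec.members_per_family:
            guard += 1
            if guard > 1000:
                raise RuntimeError("family variant generation failed to converge")
            if not positions:
                break  # divergence 0: family of identical CDR3s is impossible
            k = int(rng.integers(1, len(positions) + 1))
            subset = [positions[i] for i in
                      sorted(rng.choice(len(positions), size=k, replace=False))]
            vnt, vaa = _mutate_cdr3(nt, subset, rng, params)
            key = (el.bestVHit, el.bestJHit, vnt)
            if key in member_keys or key in existing:
                continue
            member_keys.add(key)
            members.append((vnt, vaa))
        for mnt, maa in members:
            spiked.append(Clonotype(chain=chain, v_call=el.bestVHit,
                                    j_call=el.bestJHit,
                                    d_call=el.bestDHit or None,
                                    cdr3_nt=mnt, cdr3_aa=maa,
                                    count=spike_count, frequency=0.0,
                                    sample_id=rep.sample_id, elements=None))
            truth_rows.append(dict(family_id=family_id, v_call=el.bestVHit,
                                   j_call=el.bestJHit, cdr3_nt=mnt,
                                   cdr3_aa=maa))
        existing |= member_keys
    combined = Repertoire.build(list(rep.clonotypes) + spiked,
                                sample_id=rep.sample_id,
                                condition=rep.condition)
    truth = pd.DataFrame(truth_rows,
                         columns=["family_id", "v_call", "j_call", "cdr3_nt",
                                  "cdr3_aa"])
    return combined, truth


def resample_culture(rep: Repertoire, depth: int, rng: np.random.Generator,
                     sample_id: str, condition: str = "",
                     dropout_max_count: int = 4,
                     dropout_prob: float = 0.6) -> Repertoire:
    """One culture replicate: random dropout of low-abundance clones followed
    by multinomial resampling of read counts at ``depth``.

    Clones with ``count <= dropout_max_count`` are independently lost with
    probability ``dropout_prob`` (strong culture-specific effects on clonal
    frequencies); surviving clones are then sequenced to ``depth`` reads.
    """
    survived = []
    for c in rep.clonotypes:
        if c.count <= dropout_max_count and rng.random() < dropout_prob:
            continue
        survived.append(c)
    if not survived:
        raise ValueError("culture dropout removed every clonotype")
    freqs = np.array([c.frequency for c in survived])
    counts = rng.multinomial(depth, freqs / freqs.sum())
    kept = [c.with_frequency(0.0, count=int(k))
            for c, k in zip(survived, counts) if k > 0]
    return Repertoire.build(kept, sample_id=sample_id, condition=condition)


def make_condition_pair(background: Repertoire, spec: SpikeSpec,
                        seed: Optional[int] = None,
                        rng: Optional[np.random.Generator] = None,
                        depth: Optional[int] = None,
                        nt_table: Optional[GermlineNtTable] = None,
                        params: TcrdistParams = TcrdistParams(),
                        ) -> Tuple[Repertoire, Repertoire, pd.DataFrame]:
    """Matched antigen-negative / antigen-positive culture pair.

    Both conditions apply independent culture noise (random dropout of
    low-abundance clones, then deep multinomial resampling), so most
    low-frequency clonotypes end up unique to one condition; the Ag+
    condition additionally carries the spiked families. The default depth of
    20 reads per latent clonotype keeps the detection floor well below
    spiked-family frequencies, as deep culture sequencing does.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    depth = depth if depth is not None else 20 * len(background)
    ag_minus = resample_culture(background, depth, rng,
                                sample_id=f"{background.sample_id}_AgNeg",
                                condition="Ag-")
    ag_plus_latent, truth = spike_families(background, spec, rng=rng,
                                           nt_table=nt_table, params=params)
    ag_plus = resample_culture(ag_plus_latent, depth, rng,
                               sample_id=f"{background.sample_id}_AgPos",
                               condition="Ag+")
    return ag_minus, ag_plus, truth
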