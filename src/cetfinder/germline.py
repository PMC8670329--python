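"""Germline reference tables: V-gene CDR loops and CDR3-proximal nucleotides.

Two small references are needed. The CDR table maps each V gene to its
germline-encoded CDR1, CDR2 and CDR2.5 loops (identifiable from IMGT
alignments), which the distance metric scores alongside the junction-encoded
CDR3. The nucleotide table holds the CDR3-proximal germline sequence of each
V gene (from the conserved cysteine codon), the CDR3 suffix of each J gene
(through the conserved F/W codon) and the TRBD segments; the null model uses
it to reassemble junctions from recombination elements.

The bundled ``synthetic_germline_*.tsv`` files are a synthetic stand-in
reference: gene names follow human nomenclature but loop/nucleotide content
is generated, sufficient for simulation and testing. Real analyses should
load an IMGT-derived table via :func:`load_cdr_table` /
:func:`load_nt_table`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Tuple

import pandas as pd

from .repertoire import strip_allele, translate


@dataclass(frozen=True)
class GermlineCdrTable:
    """Mapping (chain, V gene) -> (cdr1, cdr2, cdr2_5) amino-acid loops."""

    loops: Dict[Tuple[str, str], Tuple[str, str, str]] = field(default_factory=dict)

    def get(self, v_call: str, chain: str) -> Tuple[str, str, str]:
        gene = strip_allele(v_call)
        try:
            return self.loops[(chain, gene)]
        except KeyError:
            raise KeyError(
                f"V gene {gene!r} ({chain}) has no entry in the germline CDR "
                f"table; supply a table covering every V call in the shortlist"
            ) from None

    def __contains__(self, item: Tuple[str, str]) -> bool:
        chain, v_call = item
        return (chain, strip_allele(v_call)) in self.loops

    def genes(self, chain: str):
        return sorted(g for (c, g) in self.loops if c == chain)


@dataclass(frozen=True)
class GermlineNtTable:
    """CDR3-proximal germline nucleotide sequences for junction reassembly."""

    v_cdr3: Dict[Tuple[str, str], str] = field(default_factory=dict)
    j_cdr3: Dict[Tuple[str, str], str] = field(default_factory=dict)
    d_seg: Dict[str, str] = field(default_factory=dict)

    def v_prefix(self, v_call: str, chain: str) -> str:
        gene = strip_allele(v_call)
        try:
            return self.v_cdr3[(chain, gene)]
        except KeyError:
            raise KeyError(f"no germline CDR3 prefix for V gene {gene!r} ({chain})") from None

    def j_suffix(self, j_call: str, chain: str) -> str:
        gene = strip_allele(j_call)
        try:
            return self.j_cdr3[(chain, gene)]
        except KeyError:
            raise KeyError(f"no germline CDR3 suffix for J gene {gene!r} ({chain})") from None

    def d(self, d_call: str) -> str:
        gene = strip_allele(d_call)
        try:
            return self.d_seg[gene]
        except KeyError:
            raise KeyError(f"no germline sequence for D gene {gene!r}") from None

    def v_genes(self, chain: str):
        return sorted(g for (c, g) in self.v_cdr3 if c == chain)

    def j_genes(self, chain: str):
        return sorted(g for (c, g) in self.j_cdr3 if c == chain)


def load_cdr_table(path) -> GermlineCdrTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "chain", "cdr1", "cdr2", "cdr2_5"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"germline CDR table missing columns: {sorted(missing)}")
    loops = {
        (row.chain, strip_allele(row.gene)): (row.cdr1, row.cdr2, row.cdr2_5)
        for row in df.itertuples()
    }
    return GermlineCdrTable(loops)


def load_nt_table(path) -> GermlineNtTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "chain", "region", "nt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"germline nt table missing columns: {sorted(missing)}")
    v: Dict[Tuple[str, str], str] = {}
    j: Dict[Tuple[str, str], str] = {}
    d: Dict[str, str] = {}
    for row in df.itertuples():
        gene = strip_allele(row.gene)
        if row.region == "v_cdr3":
            v[(row.chain, gene)] = row.nt
        elif row.region == "j_cdr3":
            j[(row.chain, gene)] = row.nt
        elif row.region == "d_seg":
            d[gene] = row.nt
        else:
            raise ValueError(f"unknown germline region {row.region!r}")
    return GermlineNtTable(v, j, d)


def _data_path(name: str):
    return resources.files("cetfinder.data").joinpath(name)


def synthetic_cdr_table() -> GermlineCdrTable:
    """The bundled synthetic V-gene CDR loop table (simulation/testing)."""
    with resources.as_file(_data_path("synthetic_germline_cdr.tsv")) as p:
        return load_cdr_table(p)


def synthetic_nt_table() -> GermlineNtTable:
    """The bundled synthetic CDR3-proximal nucleotide table (simulation/testing)."""
    with resources.as_file(_data_path("synthetic_germline_nt.tsv")) as p:
        return load_nt_table(p)


def v_prefix_aa(nt_table: GermlineNtTable, v_call: str, chain: str) -> str:
    return translate(nt_table.v_prefix(v_call, chain))
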