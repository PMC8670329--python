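"""Reading and writing clonotype tables in standard and vendor dialects.

Three input dialects are supported, all tab-separated:

* ``airr`` — AIRR Rearrangement columns (v_call, d_call, j_call, junction,
  junction_aa, duplicate_count).
* ``vendor_full`` — aligner clonotype export carrying the 14
  junction-element columns needed by the null model, plus nSeqCDR3,
  aaSeqCDR3 and cloneCount.
* ``vendor_beta_genomic`` — genomic-DNA TCRβ export (v_gene, j_gene,
  cdr3_rearrangement, cdr3_amino_acid, templates); template counts map to
  ``count``, which is equivalent for the pipeline.

Rows sharing the clonotype identity key (v_call, j_call, cdr3_nt) are merged
with summed counts before anything else; frequencies are recomputed over the
retained (productive, merged) rows of each sample independently.
"""
from __future__ import annotations

import logging
from typing import Dict, Optional, Sequence

import pandas as pd

from .nullmodel import ELEMENT_SLOTS, decompose
from .repertoire import (Clonotype, Repertoire, chain_of_call, translate)
from .significance import Cet

logger = logging.getLogger(__name__)

DIALECTS = ("airr", "vendor_full", "vendor_beta_genomic")

_AIRR_COLS = ("v_call", "j_call", "junction", "junction_aa", "duplicate_count")
_VENDOR_FULL_COLS = ("bestVHit", "bestJHit", "nSeqCDR3", "aaSeqCDR3", "cloneCount")
_BETA_GENOMIC_COLS = ("v_gene", "j_gene", "cdr3_rearrangement",
                      "cdr3_amino_acid", "templates")

CET_TABLE_COLUMNS = ["sample_id", "condition", "chain", "v_call", "d_call",
                     "j_call", "cdr3_nt", "cdr3_aa", "count", "frequency",
                     "cet_id", "threshold", "cluster_size", "geo_mean_freq",
                     "p_value"]


class FormatError(ValueError):
    pass


class EmptyInputError(ValueError):
    pass


def _require(df: pd.DataFrame, columns: Sequence[str], dialect: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(
            f"{dialect} table is missing required column(s): {', '.join(missing)}")


def _clean(v) -> str:
    return "" if v is None or v != v else str(v)


def _rows_airr(df: pd.DataFrame, chain: Optional[str]):
    _require(df, _AIRR_COLS, "airr")
    for row in df.to_dict("records"):
        v = _clean(row["v_call"])
        nt = _clean(row["junction"]).upper()
        yield dict(v_call=v, j_call=_clean(row["j_call"]),
                   d_call=_clean(row.get("d_call")) or None,
                   cdr3_nt=nt, cdr3_aa=_clean(row["junction_aa"]),
                   count=int(row["duplicate_count"]),
                   chain=chain or chain_of_call(v), elements=None)


def _rows_vendor_full(df: pd.DataFrame, chain: Optional[str]):
    _require(df, _VENDOR_FULL_COLS, "vendor_full")
    has_elements = all(c in df.columns for c in ELEMENT_SLOTS)
    for row in df.to_dict("records"):
        v = _clean(row["bestVHit"])
        elements = None
        if has_elements and _clean(row.get("bestVHit")):
            try:
                elements = decompose(row)
            except (KeyError, ValueError):
                elements = None
        yield dict(v_call=v, j_call=_clean(row["bestJHit"]),
                   d_call=_clean(row.get("bestDHit")) or None,
                   cdr3_nt=_clean(row["nSeqCDR3"]).upper(),
                   cdr3_aa=_clean(row["aaSeqCDR3"]),
                   count=int(row["cloneCount"]),
                   chain=chain or chain_of_call(v), elements=elements)


def _rows_beta_genomic(df: pd.DataFrame, chain: Optional[str]):
    _require(df, _BETA_GENOMIC_COLS, "vendor_beta_genomic")
    for row in df.to_dict("records"):
        v = _clean(row["v_gene"])
        yield dict(v_call=v, j_call=_clean(row["j_gene"]), d_call=None,
                   cdr3_nt=_clean(row["cdr3_rearrangement"]).upper(),
                   cdr3_aa=_clean(row["cdr3_amino_acid"]),
                   count=int(row["templates"]),
                   chain="beta", elements=None)


_ROW_PARSERS = {"airr": _rows_airr, "vendor_full": _rows_vendor_full,
                "vendor_beta_genomic": _rows_beta_genomic}


def read_clonotype_table(path, dialect: str = "airr",
                         productive_only: bool = True,
                         sample_id: Optional[str] = None,
                         condition: str = "",
                         chain: Optional[str] = None) -> Repertoire:
    """Parse a clonotype TSV into a normalised Repertoire.

    Duplicate (v_call, j_call, cdr3_nt) rows are merged with summed counts;
    non-productive rows (stop codon in the CDR3, or out-of-frame junction)
    are dropped when ``productive_only``; frequencies are recomputed over the
    retained rows.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df.empty:
        raise EmptyInputError(f"clonotype table {path} contains no rows")
    sid = sample_id if sample_id is not None else str(path)

    merged: Dict[tuple, dict] = {}
    for rec in _ROW_PARSERS[dialect](df, chain):
        if rec["chain"] is None:
            raise FormatError(
                f"cannot infer chain from V call {rec['v_call']!r}; pass chain=")
        nt, aa = rec["cdr3_nt"], rec["cdr3_aa"]
        if not aa and nt and len(nt) % 3 == 0:
            aa = rec["cdr3_aa"] = translate(nt)
        if productive_only:
            if not nt or len(nt) % 3 or "*" in aa:
                continue
        key = (rec["v_call"], rec["j_call"], nt)
        if key in merged:
            merged[key]["count"] += rec["count"]
        else:
            merged[key] = rec
    if not merged:
        raise EmptyInputError(f"no clonotypes retained from {path}")
    clons = [Clonotype(chain=r["chain"], v_call=r["v_call"], j_call=r["j_call"],
                       d_call=r["d_call"], cdr3_nt=r["cdr3_nt"],
                       cdr3_aa=r["cdr3_aa"], count=r["count"], frequency=0.0,
                       sample_id=sid, elements=r["elements"])
             for r in merged.values()]
    return Repertoire.build(clons, sample_id=sid, condition=condition)


def shortlist_top(rep: Repertoire, n: int) -> Repertoire:
    """The n most frequent clonotypes (sample-level frequencies retained).

    Boundary ties are broken by lexicographic (cdr3_nt, v_call, j_call)
    order — the repertoire's canonical ordering. If fewer than n clonotypes
    exist, all are retained and a warning is logged.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(rep) < n:
        logger.warning("shortlist_top: repertoire %s has only %d clonotypes "
                       "(< %d); retaining all", rep.sample_id, len(rep), n)
        return rep
    return Repertoire(sample_id=rep.sample_id, clonotypes=rep.clonotypes[:n],
                      condition=rep.condition, total_reads=rep.total_reads)


def write_clonotype_table(rep: Repertoire, path, dialect: str = "vendor_full") -> None:
    """Write a repertoire in one of the supported dialects (byte-stable)."""
    rows = []
    if dialect == "airr":
        for c in rep:
            rows.append(dict(v_call=c.v_call, d_call=c.d_call or "",
                             j_call=c.j_call, junction=c.cdr3_nt,
                             junction_aa=c.cdr3_aa, duplicate_count=c.count))
    elif dialect == "vendor_full":
        for c in rep:
            row = dict(bestVHit=c.v_call, bestDHit=c.d_call or "",
                       bestJHit=c.j_call, nSeqCDR3=c.cdr3_nt,
                       aaSeqCDR3=c.cdr3_aa, cloneCount=c.count)
            if c.elements is not None:
                row.update(c.elements.as_dict())
            else:
                for slot in ELEMENT_SLOTS:
                    if slot not in row:
                        row[slot] = ""
            rows.append(row)
    elif dialect == "vendor_beta_genomic":
        for c in rep:
            rows.append(dict(v_gene=c.v_call, j_gene=c.j_call,
                             cdr3_rearrangement=c.cdr3_nt,
                             cdr3_amino_acid=c.cdr3_aa, templates=c.count))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_cet_table(cets: Sequence[Cet], path) -> None:
    """One row per (CET, member clonotype); header-only file for no CETs."""
    rows = []
    for cet in cets:
        for m in cet.members:
            rows.append(dict(sample_id=cet.sample_id or m.sample_id,
                             condition=cet.condition, chain=m.chain,
                             v_call=m.v_call, d_call=m.d_call or "",
                             j_call=m.j_call, cdr3_nt=m.cdr3_nt,
                             cdr3_aa=m.cdr3_aa, count=m.count,
                             frequency=m.frequency, cet_id=cet.cet_id,
                             threshold=cet.threshold,
                             cluster_size=cet.n_members,
                             geo_mean_freq=cet.geo_mean_freq,
                             p_value="" if cet.p_value is None else cet.p_value))
    pd.DataFrame(rows, columns=CET_TABLE_COLUMNS).to_csv(path, sep="\t",
                                                         index=False)


def read_cet_table(path) -> pd.DataFrame:
    """Round-trip reader for CET tables written by :func:`write_cet_table`."""
    return pd.read_csv(path, sep="\t", dtype={"cdr3_nt": str, "cdr3_aa": str})
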