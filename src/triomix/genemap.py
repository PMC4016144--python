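"""Identifier unification into one gene namespace.

Protein and probe identifiers are translated to gene identifiers through a
pre-resolved mapping table; one entity may map to zero, one or several
genes.  Version suffixes (a trailing ``.N``) are stripped before lookup.
The unified table carries one row per gene with up to three technology
values, detection flags and an OR-combined multi-gene flag; unmapped
entities are tallied per technology rather than dropped silently.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

_VERSION_RE = re.compile(r"\.\d+$")

TECHNOLOGIES = ("proteomics", "array", "rnaseq")

#: per-technology rule for combining duplicate (gene, technology) rows:
#: counts add; intensities are summarized robustly
DEFAULT_AGGREGATION = {"proteomics": "sum", "array": "median", "rnaseq": "sum"}


def strip_version(identifier: str) -> str:
    """Drop a trailing .N version suffix (Ensembl dialect)."""
    return _VERSION_RE.sub("", identifier)


@dataclass
class AnnotationMap:
    """Total lookup from protein/probe identifiers to gene-id sets."""

    protein_to_genes: dict[str, set[str]] = field(default_factory=dict)
    probe_to_genes: dict[str, set[str]] = field(default_factory=dict)
    gene_info: pd.DataFrame = field(default_factory=pd.DataFrame)

    @classmethod
    def from_tables(cls, idmap: pd.DataFrame, gene_info: pd.DataFrame) -> "AnnotationMap":
        """Build from long-form idmap (entity_id, entity_type, gene_ids) and gene_info."""
        prot: dict[str, set[str]] = {}
        probe: dict[str, set[str]] = {}
        for _, row in idmap.iterrows():
            genes = {strip_version(g) for g in str(row["gene_ids"]).split(";") if g}
            target = prot if row["entity_type"] == "protein" else probe
            target[strip_version(row["entity_id"])] = genes
        gi = gene_info.copy()
        gi["gene_id"] = gi["gene_id"].map(strip_version)
        return cls(prot, probe, gi.set_index("gene_id"))

    def proteins(self, protein_id: str) -> set[str]:
        return self.protein_to_genes.get(strip_version(protein_id), set())

    def probes(self, probe_id: str) -> set[str]:
        return self.probe_to_genes.get(strip_version(probe_id), set())


def _aggregate(rows: pd.DataFrame, how: str) -> pd.DataFrame:
    if len(rows) == 0:
        return pd.DataFrame(columns=["gene_id", "value", "multi_gene"])
    return (
        rows.groupby("gene_id", sort=True)
        .agg(value=("value", how), multi_gene=("multi_gene", "any"))
        .reset_index()
    )


def build_unified_table(
    gene_values: dict[str, pd.DataFrame],
    annotation: AnnotationMap,
    unmapped_tallies: dict[str, int] | None = None,
    aggregation: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Merge per-technology gene values into one matrix.

    Parameters
    ----------
    gene_values : mapping technology -> table with columns gene_id, value,
        multi_gene (already in the gene namespace).
    annotation : supplies biotype/description per gene; genes missing from
        it are retained with unknown biotype (with a warning).
    unmapped_tallies : per-technology counts of entities that could not be
        mapped to any gene (carried through into the returned tallies).
    aggregation : per-technology reduction for duplicate gene rows;
        defaults to sum for count technologies and median for the array.

    Returns ``(unified, tallies)``. ``unified`` has one row per gene:
    ``gene_id, biotype, <tech>_value, <tech>_detected, multi_gene``.
    """
    agg = dict(DEFAULT_AGGREGATION)
    if aggregation:
        agg.update(aggregation)
    tallies = dict(unmapped_tallies or {})

    merged: pd.DataFrame | None = None
    for tech in TECHNOLOGIES:
        rows = gene_values.get(tech)
        if rows is None or len(rows) == 0:
            rows = pd.DataFrame(columns=["gene_id", "value", "multi_gene"])
        part = _aggregate(rows, agg[tech]).rename(
            columns={"value": f"{tech}_value", "multi_gene": f"{tech}_multi"}
        )
        merged = part if merged is None else merged.merge(part, on="gene_id", how="outer")

    multi = pd.Series(False, index=merged.index)
    for t in TECHNOLOGIES:
        multi |= merged[f"{t}_multi"].eq(True)
    merged["multi_gene"] = multi
    for tech in TECHNOLOGIES:
        merged[f"{tech}_value"] = pd.to_numeric(merged[f"{tech}_value"])
        merged[f"{tech}_detected"] = merged[f"{tech}_value"].notna()
        merged = merged.drop(columns=[f"{tech}_multi"])

    info = annotation.gene_info
    if len(info):
        merged = merged.merge(
            info[["biotype"]], left_on="gene_id", right_index=True, how="left"
        )
        unknown = merged["biotype"].isna()
        if unknown.any():
            warnings.warn(
                f"{int(unknown.sum())} gene id(s) missing from gene_info; biotype set to unknown",
                stacklevel=2,
            )
        merged["biotype"] = merged["biotype"].fillna("unknown")
    else:
        merged["biotype"] = "unknown"

    cols = (
        ["gene_id", "biotype"]
        + [f"{t}_value" for t in TECHNOLOGIES]
        + [f"{t}_detected" for t in TECHNOLOGIES]
        + ["multi_gene"]
    )
    return merged[cols].sort_values("gene_id", kind="stable").reset_index(drop=True), tallies


def exclude_noncoding(unified: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Restrict the comparison set to protein-coding genes.

    Returns ``(protein-coding subset, number of noncoding genes removed)``;
    genes of unknown biotype are kept.
    """
    noncoding = unified["biotype"].eq("noncoding")
    return unified.loc[~noncoding].reset_index(drop=True), int(noncoding.sum())
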