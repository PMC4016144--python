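"""Readers and writers for the pipeline's on-disk formats.

All tables travel as plain TSV. Read alignments use BED6 (0-based
half-open); gene models use GFF3 (1-based inclusive on disk, converted to
0-based half-open on read). GFF3 parsing goes through :mod:`gffutils`.
"""

from __future__ import annotations

import os
from typing import Iterable

import gffutils
import pandas as pd


class SchemaError(ValueError):
    """An input table does not match the expected schema."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def read_psms(path: str) -> pd.DataFrame:
    """Read a PSM table: spectrum_id, peptide, proteins (';'-joined), probability, is_decoy."""
    df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str, "peptide": str, "proteins": str})
    _require_columns(df, ["spectrum_id", "peptide", "proteins", "probability", "is_decoy"], path)
    bad = df["probability"].lt(0) | df["probability"].gt(1) | df["probability"].isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise SchemaError(f"{path}: line {line}, column 'probability': value outside [0, 1]")
    if df["proteins"].fillna("").eq("").any():
        line = int(df["proteins"].fillna("").eq("").idxmax()) + 2
        raise SchemaError(f"{path}: line {line}, column 'proteins': empty protein group")
    if df["spectrum_id"].duplicated().any():
        dup = df.loc[df["spectrum_id"].duplicated(), "spectrum_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate spectrum_id {dup!r}")
    return df


def write_psms(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_probes(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "array_id": str})
    _require_columns(df, ["probe_id", "array_id", "fg_cy3", "bg_cy3", "fg_cy5", "bg_cy5"], path)
    for col in ("fg_cy3", "bg_cy3", "fg_cy5", "bg_cy5"):
        bad = df[col].lt(0) | df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise SchemaError(f"{path}: line {line}, column {col!r}: negative or missing intensity")
    return df


def read_probe_annotation(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["probe_id", "gene_ids"], path)
    return df


def read_idmap(path: str) -> pd.DataFrame:
    """entity_id, entity_type in {protein, probe}, gene_ids (';'-joined, may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["entity_id", "entity_type", "gene_ids"], path)
    bad = ~df["entity_type"].isin(["protein", "probe"])
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise SchemaError(f"{path}: line {line}, column 'entity_type': expected 'protein' or 'probe'")
    return df


def read_gene_info(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["gene_id", "biotype", "description", "go_cc_terms"], path)
    return df


def read_bed(path: str) -> pd.DataFrame:
    """Read BED6 alignments into chrom/start/end/read_id/score/strand."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "read_id", "score", "strand"],
        dtype={"chrom": str, "read_id": str, "strand": str},
    )
    if (df["start"] >= df["end"]).any():
        line = int((df["start"] >= df["end"]).idxmax()) + 1
        raise SchemaError(f"{path}: line {line}: interval start >= end")
    return df


def write_bed(reads: pd.DataFrame, path: str) -> None:
    reads[["chrom", "start", "end", "read_id", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_gff3(annotation: pd.DataFrame, path: str) -> None:
    """Write gene/exon features; input coordinates are 0-based half-open."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        genes = annotation[annotation["feature"] == "gene"]
        exons = annotation[annotation["feature"] == "exon"]
        exon_by_gene = {g: sub for g, sub in exons.groupby("gene_id", sort=False)}
        for _, row in genes.iterrows():
            gid = row["gene_id"]
            fh.write(
                f"{row['chrom']}\tsim\tgene\t{row['start'] + 1}\t{row['end']}\t.\t+\t.\t"
                f"ID={gid};biotype={row['biotype']}\n"
            )
            for j, (_, ex) in enumerate(exon_by_gene.get(gid, pd.DataFrame()).iterrows()):
                fh.write(
                    f"{ex['chrom']}\tsim\texon\t{ex['start'] + 1}\t{ex['end']}\t.\t+\t.\t"
                    f"ID={gid}.e{j + 1};Parent={gid}\n"
                )


def read_gff3(path: str) -> pd.DataFrame:
    """Parse gene/exon features into the internal 0-based half-open table.

    Returns columns gene_id, chrom, start, end, feature, biotype. Exons are
    attached to their gene via Parent (falling back to a gene_id attribute).
    """
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    rows = []
    biotypes = {}
    for g in db.features_of_type("gene"):
        bt = g.attributes.get("biotype", ["protein_coding"])[0]
        biotypes[g.id] = bt
        rows.append((g.id, g.seqid, g.start - 1, g.end, "gene", bt))
    for e in db.features_of_type("exon"):
        parents = e.attributes.get("Parent") or e.attributes.get("gene_id")
        if not parents:
            raise SchemaError(f"{path}: exon {e.id} has neither Parent nor gene_id attribute")
        gid = parents[0]
        rows.append((gid, e.seqid, e.start - 1, e.end, "exon", biotypes.get(gid, "protein_coding")))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "feature", "biotype"])


def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
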