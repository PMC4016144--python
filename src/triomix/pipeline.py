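"""End-to-end orchestration: simulate or load inputs, run the three
quantification stages, unify to the gene namespace and compare.

One YAML-able configuration dict drives everything; identical configuration
(including the seed) yields identical outputs and an identical
machine-readable run report.  Stage timings and progress go to stderr.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from typing import Any

import numpy as np
import pandas as pd

from triomix import io as tio
from triomix.concordance import (
    annotate_categories,
    concordance_with_exclusions,
    region_summaries,
    venn_partition,
)
from triomix.genemap import AnnotationMap, build_unified_table, exclude_noncoding
from triomix.microarray import array_expression
from triomix.proteomics import expand_groups, filter_psms, spectral_count
from triomix.rnaseq import count_reads_per_gene, filter_quantified_genes, gene_models_from_annotation
from triomix.simulate import SimConfig, simulate_array, simulate_ground_truth, simulate_idmap, simulate_psms, simulate_reads

REPORT_SCHEMA_VERSION = 1

logger = logging.getLogger("triomix")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2fs", name, dt)
                return False
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return _Timer()


def run_from_frames(
    psms: pd.DataFrame,
    probes: pd.DataFrame,
    probe_annotation: pd.DataFrame,
    reads: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    idmap: pd.DataFrame,
    gene_info: pd.DataFrame,
    params: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Run proteomics -> array -> rnaseq -> unify -> compare on in-memory tables.

    Returns a dict with the unified table, per-stage tables and the report
    payload (everything :func:`run_all` writes to disk).
    """
    p = params or {}
    prot_p = p.get("proteomics", {})
    arr_p = p.get("array", {})
    rna_p = p.get("rnaseq", {})
    cmp_p = p.get("compare", {})

    annotation = AnnotationMap.from_tables(idmap, gene_info)

    with _stage("proteomics"):
        accepted, fdr = filter_psms(
            psms,
            min_probability=prot_p.get("min_probability", 0.95),
            max_fdr=prot_p.get("max_fdr", 0.01),
        )
        protein_quant = spectral_count(accepted)
        ms_rows, n_unmapped_proteins = expand_groups(protein_quant, annotation.protein_to_genes)
        min_sc = prot_p.get("min_spectral_count", 1)
        ms_rows = ms_rows.loc[ms_rows["value"] >= min_sc].reset_index(drop=True)
        # spectra whose entire protein group lacks a gene annotation
        if len(accepted):
            group_unmapped = {
                s: all(not annotation.proteins(pid) for pid in str(s).split(";") if pid)
                for s in accepted["proteins"].unique()
            }
            n_unmapped_spectra = int(accepted["proteins"].map(group_unmapped).sum())
        else:
            n_unmapped_spectra = 0

    with _stage("array"):
        if len(probes):
            probe_map = {
                p: {g for g in str(gs).split(";") if g}
                for p, gs in zip(probe_annotation["probe_id"], probe_annotation["gene_ids"])
            }
            arr_rows, unannotated_probes = array_expression(
                probes,
                probe_map,
                span=arr_p.get("span", 0.3),
                probe_stat=arr_p.get("probe_stat", "median"),
            )
            min_int = arr_p.get("min_intensity", 0.0)
            arr_rows = arr_rows.loc[arr_rows["value"] >= min_int].reset_index(drop=True)
        else:
            arr_rows = pd.DataFrame(columns=["gene_id", "value", "multi_gene"])
            unannotated_probes = pd.DataFrame(columns=["array_id", "n_unannotated"])

    with _stage("rnaseq"):
        models = gene_models_from_annotation(gene_annotation)
        count_res = count_reads_per_gene(reads, models, min_overlap=rna_p.get("min_overlap", 1))
        quantified, filter_report = filter_quantified_genes(
            count_res.counts, count_res.detected_loci, min_count=rna_p.get("min_count", 1)
        )
        rna_rows = count_res.counts.loc[
            count_res.counts["gene_id"].isin(quantified)
        ].rename(columns={"count": "value"})
        rna_rows["multi_gene"] = False

    with _stage("unify"):
        unmapped_tallies = {
            "proteomics_proteins": n_unmapped_proteins,
            "proteomics_spectra": n_unmapped_spectra,
            "array_probes": int(unannotated_probes["n_unannotated"].sum())
            if len(unannotated_probes)
            else 0,
        }
        unified, tallies = build_unified_table(
            {"proteomics": ms_rows, "array": arr_rows, "rnaseq": rna_rows},
            annotation,
            unmapped_tallies=unmapped_tallies,
            aggregation=p.get("aggregation"),
        )

    with _stage("compare"):
        coding, n_noncoding = exclude_noncoding(unified)
        categories = annotate_categories(annotation.gene_info) if len(annotation.gene_info) else pd.Series(dtype=object)
        detected = {
            t: set(unified.loc[unified[f"{t}_detected"], "gene_id"])
            for t in ("proteomics", "rnaseq", "array")
        }
        partition = venn_partition(detected, unannotated=unmapped_tallies)
        summaries = region_summaries(partition, unified)
        results = concordance_with_exclusions(
            coding, categories, universe=cmp_p.get("universe", "triple")
        )

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "stage_counts": {
            "psms_in": int(len(psms)),
            "psms_accepted": int(fdr.n_target_accepted),
            # the same spectra counted once per protein-group member
            "psm_protein_assignments": int(protein_quant["spectral_count"].sum())
            if len(protein_quant)
            else 0,
            "proteins_quantified": int(len(protein_quant)),
            "probe_rows_in": int(len(probes)),
            "read_rows_in": int(len(reads)),
            "reads_assigned": count_res.n_assigned,
            "reads_ambiguous": count_res.n_ambiguous,
            "reads_off_exon": count_res.n_off_exon,
            "reads_unknown_chrom": count_res.n_unknown_chrom,
            "rnaseq_detected_loci": len(count_res.detected_loci),
            "rnaseq_quantified_genes": len(quantified),
            "noncoding_excluded": n_noncoding,
        },
        "fdr": dataclasses.asdict(fdr),
        "genes_detected": {t: len(s) for t, s in detected.items()},
        "venn_region_sizes": partition.region_sizes,
        "venn_union_size": partition.union_size,
        "unmapped": tallies,
        "concordance": [
            {"pair": list(r.pair), "rule_set": r.rule_set,
             "rho": None if np.isnan(r.rho) else round(float(r.rho), 6),
             "n": r.n, "low_n": r.low_n}
            for r in results
        ],
    }
    return {
        "report": report,
        "unified": unified,
        "unannotated_probes": unannotated_probes,
        "protein_quant": protein_quant,
        "ms_rows": ms_rows,
        "arr_rows": arr_rows,
        "rna_rows": rna_rows,
        "filter_report": filter_report,
        "region_summaries": summaries,
        "partition": partition,
        "concordance": results,
        "fdr": fdr,
    }


def _simulate_inputs(sim_cfg: SimConfig, out_dir: str | None):
    truth = simulate_ground_truth(sim_cfg)
    psms = simulate_psms(truth, sim_cfg)
    probes, probe_annotation = simulate_array(truth, sim_cfg)
    reads, gene_annotation = simulate_reads(truth, sim_cfg)
    idmap_prot = simulate_idmap(truth, sim_cfg)
    idmap = pd.concat(
        [
            idmap_prot,
            probe_annotation.rename(columns={"probe_id": "entity_id"}).assign(entity_type="probe")[
                ["entity_id", "entity_type", "gene_ids"]
            ],
        ],
        ignore_index=True,
    )
    gene_info = truth[["gene_id", "biotype", "description", "go_cc_terms"]].copy()
    if out_dir is not None:
        tio.ensure_dir(out_dir)
        tio.write_psms(psms, os.path.join(out_dir, "psms.tsv"))
        tio.write_tsv(probes, os.path.join(out_dir, "probes.tsv"))
        tio.write_tsv(probe_annotation, os.path.join(out_dir, "probe_annotation.tsv"))
        tio.write_bed(reads, os.path.join(out_dir, "reads.bed"))
        tio.write_gff3(gene_annotation, os.path.join(out_dir, "genes.gff3"))
        tio.write_tsv(truth, os.path.join(out_dir, "truth.tsv"))
        tio.write_tsv(idmap, os.path.join(out_dir, "idmap.tsv"))
        tio.write_tsv(gene_info, os.path.join(out_dir, "gene_info.tsv"))
    return truth, psms, probes, probe_annotation, reads, gene_annotation, idmap, gene_info


def run_all(config: dict[str, Any], out_dir: str, write_inputs: bool = True) -> dict[str, Any]:
    """Execute the full pipeline from a configuration dict.

    ``config`` must contain either a ``simulate`` section (SimConfig fields;
    the top-level ``seed`` is injected) or an ``inputs`` section with file
    paths (psms, probes, probe_annotation, reads, gff, idmap, gene_info).
    Optional sections ``proteomics``, ``array``, ``rnaseq``, ``compare`` and
    ``aggregation`` tune the stages.  Outputs and ``report.json`` are
    written under ``out_dir``.  Returns the report dict.
    """
    from triomix import __version__

    tio.ensure_dir(out_dir)
    seed = int(config.get("seed", 0))

    if "simulate" in config:
        with _stage("simulate"):
            sim_kwargs = dict(config["simulate"] or {})
            sim_kwargs.setdefault("seed", seed)
            if "probes_per_gene_range" in sim_kwargs:
                sim_kwargs["probes_per_gene_range"] = tuple(sim_kwargs["probes_per_gene_range"])
            sim_cfg = SimConfig(**sim_kwargs)
            sim_dir = os.path.join(out_dir, "sim") if write_inputs else None
            (_, psms, probes, probe_annotation, reads, gene_annotation, idmap, gene_info
             ) = _simulate_inputs(sim_cfg, sim_dir)
    elif "inputs" in config:
        paths = config["inputs"]
        with _stage("load"):
            for key in ("psms", "probes", "probe_annotation", "reads", "gff", "idmap", "gene_info"):
                if key not in paths:
                    raise FileNotFoundError(f"config inputs section is missing {key!r}")
                if not os.path.exists(paths[key]):
                    raise FileNotFoundError(f"input file not found: {paths[key]}")
            psms = tio.read_psms(paths["psms"])
            probes = tio.read_probes(paths["probes"])
            probe_annotation = tio.read_probe_annotation(paths["probe_annotation"])
            reads = tio.read_bed(paths["reads"])
            gene_annotation = tio.read_gff3(paths["gff"])
            idmap = tio.read_idmap(paths["idmap"])
            gene_info = tio.read_gene_info(paths["gene_info"])
    else:
        raise PipelineError("config must contain a 'simulate' or an 'inputs' section")

    result = run_from_frames(
        psms, probes, probe_annotation, reads, gene_annotation, idmap, gene_info, params=config
    )

    report = result["report"]
    report["config"] = {k: v for k, v in config.items() if k != "inputs"} | (
        {"inputs": config["inputs"]} if "inputs" in config else {}
    )
    report["seed"] = seed
    report["tool_version"] = __version__

    tio.write_tsv(result["unified"], os.path.join(out_dir, "unified_table.tsv"))
    tio.write_tsv(result["protein_quant"], os.path.join(out_dir, "protein_quant.tsv"))
    tio.write_tsv(result["ms_rows"], os.path.join(out_dir, "gene_protein_values.tsv"))
    tio.write_tsv(result["arr_rows"], os.path.join(out_dir, "gene_array_values.tsv"))
    tio.write_tsv(result["rna_rows"], os.path.join(out_dir, "gene_counts.tsv"))
    tio.write_tsv(result["filter_report"], os.path.join(out_dir, "filter_report.tsv"))
    tio.write_tsv(result["unannotated_probes"], os.path.join(out_dir, "unannotated_probe_summary.tsv"))
    tio.write_tsv(result["region_summaries"], os.path.join(out_dir, "region_summaries.tsv"))
    venn_df = pd.DataFrame(
        sorted(result["partition"].region_of.items()), columns=["gene_id", "region"]
    )
    tio.write_tsv(venn_df, os.path.join(out_dir, "venn.tsv"))
    conc_df = pd.DataFrame(
        [
            {"pair": "~".join(r.pair), "rule_set": r.rule_set, "rho": r.rho, "n": r.n,
             "low_n": r.low_n}
            for r in result["concordance"]
        ]
    )
    tio.write_tsv(conc_df, os.path.join(out_dir, "concordance.tsv"))

    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(out_dir, "report.txt"), "w") as fh:
        fh.write(render_report(report))
    return report


def render_report(report: dict[str, Any]) -> str:
    """Human-readable rendering of the run report."""
    sc = report["stage_counts"]
    fdr = report["fdr"]
    lines = [
        f"triomix {report['tool_version']} run report (seed {report['seed']})",
        "",
        f"PSMs: {sc['psms_in']} in, {sc['psms_accepted']} accepted at p >= "
        f"{fdr['threshold']:.3f} (decoy FDR {fdr['fdr_decoy']:.4f}, model FDR "
        f"{fdr['fdr_model']:.4f}); {sc['proteins_quantified']} proteins quantified, "
        f"{sc['psm_protein_assignments']} spectrum-protein assignments",
        f"Reads: {sc['read_rows_in']} in — {sc['reads_assigned']} assigned, "
        f"{sc['reads_ambiguous']} ambiguous, {sc['reads_off_exon']} off-exon; "
        f"{sc['rnaseq_detected_loci']} detected loci, "
        f"{sc['rnaseq_quantified_genes']} genes quantified",
        f"Probes: {sc['probe_rows_in']} rows; unannotated tallies {report['unmapped']}",
        "",
        "Genes detected: "
        + ", ".join(f"{t} {n}" for t, n in sorted(report["genes_detected"].items())),
        "Venn regions: "
        + ", ".join(f"{r} {n}" for r, n in report["venn_region_sizes"].items()),
        f"Non-coding genes excluded from comparison: {sc['noncoding_excluded']}",
        "",
        "Concordance (Spearman rho):",
    ]
    for c in report["concordance"]:
        rho = "undefined" if c["rho"] is None else f"{c['rho']:.4f}"
        flag = "  [low n]" if c["low_n"] else ""
        lines.append(
            f"  {'~'.join(c['pair']):24s} {c['rule_set']:28s} rho={rho} n={c['n']}{flag}"
        )
    return "\n".join(lines) + "\n"
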