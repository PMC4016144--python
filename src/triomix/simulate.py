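"""Synthetic tri-omics data generator.

Emulates the statistical structure of a parallel transcriptome/proteome
study of whole zebrafish embryos: ~20k annotated genes, a sparsely detected
proteome (spectral counts spanning 1 to thousands, heavy-tailed), multiple
two-color array probes per gene with intensity-dependent dye bias, short
reads spread over exons of tiled gene loci, and three gene categories with
built-in mRNA/protein discordance:

* **vitellogenin** — maternally deposited yolk protein: protein abundant in
  the embryo while the mRNA (transcribed in the maternal liver) is nearly
  absent;
* **ribosomal** — transcripts over-represented relative to protein, some
  acting as untranslated RNA;
* **histone** — mRNAs are generally not polyadenylated and are depleted by
  poly-dT capture, so they are under-sampled in the sequencing library (the
  truth abundance is unchanged; the depletion acts at read sampling).

The mRNA/protein dependence of regular genes is a Gaussian copula whose
Spearman rank correlation is the controlled parameter; log-normal marginals
give realistic dynamic range. All outputs are deterministic functions of
``SimConfig`` (including its seed): each stage draws from its own seed
stream, so stages can be re-run independently and still agree byte-for-byte
with a full pipeline run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

RIBOSOME_GO_CC = "GO:0005840"

#: seed-stream indices, one per stage, so outputs are independent of call order
_STREAMS = {"truth": 0, "psms": 1, "array": 2, "reads": 3, "idmap": 4}


class ConfigError(ValueError):
    """A SimConfig field violates its invariant; the message names the field."""


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with study-scale defaults.

    Category fractions plus ``frac_noncoding`` must sum to at most 1; the
    remainder are regular protein-coding genes. ``protein_rank_corr`` is the
    Spearman correlation between true mRNA and protein abundance of regular
    coding genes (Gaussian-copula construction, so the target is analytic).
    """

    n_genes: int = 20_000
    frac_ribosomal: float = 0.020
    frac_histone: float = 0.005
    frac_vitellogenin: float = 0.002
    frac_noncoding: float = 0.05

    # log-normal marginals (natural-log scale) shared by mRNA and protein
    mrna_log_mean: float = 2.0
    mrna_log_sd: float = 2.5
    protein_rank_corr: float = 0.6

    # discordance shifts: multiplicative on the truth abundances, except the
    # histone factor which down-weights read sampling (poly-A depletion is a
    # library artifact, not a change in the underlying transcript level)
    ribosomal_mrna_factor: float = 20.0
    vitellogenin_mrna_factor: float = 0.3
    vitellogenin_protein_factor: float = 100.0
    histone_protein_factor: float = 20.0
    histone_capture_factor: float = 0.05

    # proteomics
    n_spectra_total: int = 20_000
    decoy_fraction: float = 0.10
    false_target_fraction: float | None = None  # default: matches decoy rate
    frac_shared_proteins: float = 0.08
    shared_peptide_fraction: float = 0.3
    peptides_per_protein: int = 20

    # microarray
    n_arrays: int = 4
    probes_per_gene_range: tuple[int, int] = (2, 4)
    frac_unannotated_probes: float = 0.35
    array_signal_scale: float = 50.0
    probe_affinity_log2_sd: float = 0.4
    channel_noise_log2_sd: float = 0.10
    background_mean: float = 20.0
    background_sd: float = 4.0
    dye_slope: float = 0.3
    dye_quad: float = 0.05

    # RNA-seq
    n_reads_total: int = 1_000_000
    frac_off_exon_reads: float = 0.15
    read_length: int = 60
    exon_length_range: tuple[int, int] = (150, 400)
    intron_length_range: tuple[int, int] = (100, 300)
    intergenic_gap: int = 500

    # identifier mapping
    frac_multigene_proteins: float = 0.10
    multigene_max_targets: int = 4
    frac_unmapped_proteins: float = 0.01

    # detection thresholds per technology (applied downstream)
    min_spectral_count: int = 1
    min_read_count: int = 1
    min_array_intensity: float = 0.0

    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "frac_ribosomal": self.frac_ribosomal,
            "frac_histone": self.frac_histone,
            "frac_vitellogenin": self.frac_vitellogenin,
            "frac_noncoding": self.frac_noncoding,
            "frac_unannotated_probes": self.frac_unannotated_probes,
            "frac_off_exon_reads": self.frac_off_exon_reads,
            "decoy_fraction": self.decoy_fraction,
            "frac_shared_proteins": self.frac_shared_proteins,
            "shared_peptide_fraction": self.shared_peptide_fraction,
            "frac_multigene_proteins": self.frac_multigene_proteins,
            "frac_unmapped_proteins": self.frac_unmapped_proteins,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        cat_sum = (
            self.frac_ribosomal + self.frac_histone + self.frac_vitellogenin + self.frac_noncoding
        )
        if cat_sum > 1.0 + 1e-12:
            raise ConfigError(
                f"category fractions sum to {cat_sum:.4f} > 1 "
                "(frac_ribosomal + frac_histone + frac_vitellogenin + frac_noncoding)"
            )
        if not 0.0 <= self.protein_rank_corr <= 1.0:
            raise ConfigError(f"protein_rank_corr must be in [0, 1], got {self.protein_rank_corr}")
        for name in ("n_genes", "n_spectra_total", "n_reads_total", "n_arrays", "read_length"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        lo, hi = self.probes_per_gene_range
        if not (0 <= lo <= hi):
            raise ConfigError(f"probes_per_gene_range must satisfy 0 <= lo <= hi, got {(lo, hi)}")

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the config seed."""
        return np.random.default_rng(np.random.SeedSequence((int(self.seed), _STREAMS[stage])))

    @classmethod
    def deep_coverage(cls, n_genes: int = 5_000, seed: int = 0, **overrides) -> "SimConfig":
        """Preset with near-complete detection in every technology.

        Under the sparse study-scale defaults most genes are undetected by
        LC-MS/MS, so a cross-technology correlation mixes the encoded
        mRNA/protein dependence with detection truncation.  This preset
        raises sampling depth (and narrows the abundance spread) until
        truncation and counting noise are negligible, and keeps identifier
        ambiguity (multi-gene mappings, shared peptides, unmapped ids) low so
        the exclusion rules remove few genes — the regime in which the
        pipeline should recover ``protein_rank_corr`` from the raw simulated
        files.
        """
        base = dict(
            n_genes=n_genes,
            mrna_log_sd=1.0,
            n_spectra_total=200 * n_genes,
            n_reads_total=240 * n_genes,
            frac_off_exon_reads=0.10,
            frac_unannotated_probes=0.10,
            frac_multigene_proteins=0.02,
            frac_shared_proteins=0.02,
            frac_unmapped_proteins=0.005,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)


def _largest_remainder(n: int, fracs: Sequence[float]) -> list[int]:
    """Apportion n into integer counts proportional to fracs (which sum to 1)."""
    quotas = np.asarray(fracs, dtype=float) * n
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(quotas - counts), kind="stable")
        counts[order[:short]] += 1
    return counts.tolist()


def simulate_ground_truth(config: SimConfig) -> pd.DataFrame:
    """Draw the truth layer: one row per gene.

    Columns: ``gene_id, category, biotype, mrna_abundance, protein_abundance,
    description, go_cc_terms`` (GO terms semicolon-joined). Noncoding genes
    have zero protein abundance. Category counts follow largest-remainder
    rounding of the configured fractions.
    """
    n = config.n_genes
    if n == 0:
        return pd.DataFrame(
            columns=[
                "gene_id", "category", "biotype",
                "mrna_abundance", "protein_abundance", "description", "go_cc_terms",
            ]
        )
    rng = config.rng("truth")

    frac_regular = 1.0 - (
        config.frac_ribosomal + config.frac_histone + config.frac_vitellogenin + config.frac_noncoding
    )
    n_rib, n_his, n_vit, n_nc, n_reg = _largest_remainder(
        n,
        [config.frac_ribosomal, config.frac_histone, config.frac_vitellogenin,
         config.frac_noncoding, frac_regular],
    )
    category = np.array(
        ["ribosomal"] * n_rib + ["histone"] * n_his + ["vitellogenin"] * n_vit
        + ["regular"] * (n_nc + n_reg)
    )
    biotype = np.array(["protein_coding"] * (n_rib + n_his + n_vit) + ["noncoding"] * n_nc
                       + ["protein_coding"] * n_reg)
    # shuffle so category is independent of gene index / genomic position
    perm = rng.permutation(n)
    category, biotype = category[perm], biotype[perm]

    # Gaussian copula: Spearman rho_s maps to normal correlation r = 2 sin(pi rho_s / 6)
    r = 2.0 * np.sin(np.pi * config.protein_rank_corr / 6.0)
    z1 = rng.standard_normal(n)
    z_ind = rng.standard_normal(n)
    z2 = r * z1 + np.sqrt(1.0 - r * r) * z_ind
    mrna = np.exp(config.mrna_log_mean + config.mrna_log_sd * z1)
    protein = np.exp(config.mrna_log_mean + config.mrna_log_sd * z2)

    mrna = np.where(category == "ribosomal", mrna * config.ribosomal_mrna_factor, mrna)
    mrna = np.where(category == "vitellogenin", mrna * config.vitellogenin_mrna_factor, mrna)
    protein = np.where(category == "vitellogenin", protein * config.vitellogenin_protein_factor, protein)
    protein = np.where(category == "histone", protein * config.histone_protein_factor, protein)
    protein = np.where(biotype == "noncoding", 0.0, protein)

    gene_id = np.array([f"G{i:06d}" for i in range(n)])
    desc_map = {
        "ribosomal": "40S ribosomal protein S{i}",
        "histone": "histone H2B type {i}",
        "vitellogenin": "vitellogenin {i} precursor",
        "regular": "uncharacterized protein LOC{i}",
    }
    description = np.array([desc_map[c].format(i=i) for i, c in enumerate(category)])
    description = np.where(
        (category == "regular") & (biotype == "noncoding"),
        np.array([f"long non-coding RNA LNC{i}" for i in range(n)]),
        description,
    )
    go_cc = np.where(category == "ribosomal", RIBOSOME_GO_CC, "")

    return pd.DataFrame(
        {
            "gene_id": gene_id,
            "category": category,
            "biotype": biotype,
            "mrna_abundance": mrna,
            "protein_abundance": protein,
            "description": description,
            "go_cc_terms": go_cc,
        }
    )


def simulate_idmap(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Protein/probe -> gene mapping table (long form).

    Columns: ``entity_id, entity_type, gene_ids`` (semicolon-joined; empty
    string for unmapped).  Every protein-coding gene owns one protein
    ``PRO_<gene>``; a configured fraction of proteins also map to a second
    (paralogous) gene, and a configured fraction are left out of the map
    entirely, emulating identifiers missing from the gene annotation.
    Probe annotations are emitted by :func:`simulate_array` alongside the
    intensities; this table carries the protein side plus a copy of the
    probe annotation when available.
    """
    rng = config.rng("idmap")
    coding = truth.loc[truth["biotype"] == "protein_coding", "gene_id"].to_numpy()
    rows = []
    n_coding = len(coding)
    multi = rng.random(n_coding) < config.frac_multigene_proteins
    unmapped = rng.random(n_coding) < config.frac_unmapped_proteins
    n_extra = rng.integers(1, max(config.multigene_max_targets, 2), size=n_coding)
    partners = rng.integers(0, max(n_coding, 1), size=(n_coding, max(config.multigene_max_targets - 1, 1)))
    for i, g in enumerate(coding):
        pid = f"PRO_{g}"
        if unmapped[i]:
            rows.append((pid, "protein", ""))
            continue
        genes = [g]
        if multi[i] and n_coding > 1:
            for j in partners[i, : n_extra[i]]:
                if coding[j] != g and coding[j] not in genes:
                    genes.append(coding[j])
        rows.append((pid, "protein", ";".join(genes)))
    return pd.DataFrame(rows, columns=["entity_id", "entity_type", "gene_ids"])


def simulate_psms(truth: pd.DataFrame, config: SimConfig,
                  idmap: pd.DataFrame | None = None) -> pd.DataFrame:
    """Draw one peptide-spectrum match per simulated spectrum.

    Spectra are allocated to proteins multinomially in proportion to true
    protein abundance. A configured fraction of spectra are decoy matches;
    among target matches a further fraction are incorrect (drawn with the
    same low-probability distribution as decoys — the symmetry that makes
    decoy counting an unbiased FDR estimate).  Output columns:
    ``spectrum_id, peptide, proteins, probability, is_decoy, is_correct``
    (``proteins`` semicolon-joined; ``is_correct`` is the hidden truth flag
    used only for calibration checks downstream code must not rely on).
    """
    if config.n_spectra_total == 0:
        return pd.DataFrame(
            columns=["spectrum_id", "peptide", "proteins", "probability", "is_decoy", "is_correct"]
        )
    if len(truth) == 0:
        raise ValueError("no detectable proteome: truth table is empty")
    abundance = truth["protein_abundance"].to_numpy(dtype=float)
    if abundance.sum() <= 0:
        raise ValueError("no detectable proteome: all protein abundances are zero")
    rng = config.rng("psms")
    n = config.n_spectra_total
    genes = truth["gene_id"].to_numpy()

    u = rng.random(n)
    is_decoy = u < config.decoy_fraction
    ftf = config.false_target_fraction
    if ftf is None:
        ftf = config.decoy_fraction / max(1.0 - config.decoy_fraction, 1e-12)
        ftf = min(ftf, 1.0)
    is_false_target = (~is_decoy) & (rng.random(n) < ftf)
    is_correct = ~(is_decoy | is_false_target)

    # correct spectra follow protein abundance; incorrect matches hit a
    # uniformly random protein (a wrong hit carries no abundance signal)
    p = abundance / abundance.sum()
    gene_idx = np.empty(n, dtype=int)
    gene_idx[is_correct] = rng.choice(len(genes), size=int(is_correct.sum()), p=p)
    n_wrong = int((~is_correct).sum())
    eligible = np.flatnonzero(abundance > 0)
    gene_idx[~is_correct] = rng.choice(eligible, size=n_wrong)

    # identification probabilities: targets high, decoys/false targets low
    prob = np.empty(n)
    n_corr = int(is_correct.sum())
    prob[is_correct] = 1.0 - rng.beta(0.5, 25.0, size=n_corr)
    lowmask = ~is_correct
    low = rng.beta(1.0, 8.0, size=n_wrong)
    unif = rng.random(n_wrong) < 0.10  # slab reaching high probabilities
    low[unif] = rng.random(int(unif.sum()))
    prob[lowmask] = low
    prob = np.clip(prob, 0.0, 1.0)

    pep_idx = rng.integers(1, config.peptides_per_protein + 1, size=n)
    proteins = np.array([f"PRO_{g}" for g in genes[gene_idx]], dtype=object)
    peptides = np.array(
        [f"PEP{gi}_{pi}" for gi, pi in zip(gene_idx, pep_idx)], dtype=object
    )
    decoy_ids = np.flatnonzero(is_decoy)
    for k in decoy_ids:
        proteins[k] = f"DECOY_{gene_idx[k]}"
        peptides[k] = f"XEP{gene_idx[k]}_{pep_idx[k]}"

    # shared peptides belong to paralogous protein pairs: a fixed fraction of
    # proteins has a partner, and a fixed slice of their peptide repertoire is
    # indistinguishable between the two — so whether a protein yields shared
    # spectra is a property of the protein, not of sampling depth
    n_genes_total = len(genes)
    coding_idx = np.flatnonzero(truth["protein_abundance"].to_numpy(dtype=float) > 0)
    if len(coding_idx) > 1 and config.frac_shared_proteins > 0:
        gene_is_shared = rng.random(n_genes_total) < config.frac_shared_proteins
        shift = int(rng.integers(1, len(coding_idx)))
        pos_in_coding = np.full(n_genes_total, -1)
        pos_in_coding[coding_idx] = np.arange(len(coding_idx))
        n_shared_peps = int(round(config.shared_peptide_fraction * config.peptides_per_protein))
        shared = (~is_decoy) & gene_is_shared[gene_idx] & (pep_idx <= n_shared_peps)
        for k in np.flatnonzero(shared):
            gi = gene_idx[k]
            gj = coding_idx[(pos_in_coding[gi] + shift) % len(coding_idx)]
            if gj != gi:
                proteins[k] = f"PRO_{genes[gi]};PRO_{genes[gj]}"

    return pd.DataFrame(
        {
            "spectrum_id": [f"S{i:07d}" for i in range(n)],
            "peptide": peptides,
            "proteins": proteins,
            "probability": prob,
            "is_decoy": is_decoy.astype(int),
            "is_correct": is_correct.astype(int),
        }
    )


def simulate_array(truth: pd.DataFrame, config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-channel probe intensities for each array, plus probe annotation.

    Each gene receives *k* probes (uniform in ``probes_per_gene_range``,
    shared across arrays as on a fixed array design). Both channels carry
    the same sample (a control-vs-control hybridization): channel signal =
    ``array_signal_scale * mrna * probe_affinity`` warped by an
    intensity-dependent dye distortion ``b(a) = dye_slope*(a - ā) +
    dye_quad*(a - ā)²`` applied as ±b/2 on log2 Cy5/Cy3, times log-normal
    channel noise, plus an additive background that is reported exactly in
    the ``bg_*`` columns. A configured fraction of probes is left without a
    gene annotation.

    Returns ``(probes, probe_annotation)``; probes has columns
    ``probe_id, array_id, fg_cy3, bg_cy3, fg_cy5, bg_cy5``; the annotation
    has ``probe_id, gene_ids`` (semicolon-joined, empty when unannotated).
    """
    rng = config.rng("array")
    lo, hi = config.probes_per_gene_range
    n_genes = len(truth)
    cols = ["probe_id", "array_id", "fg_cy3", "bg_cy3", "fg_cy5", "bg_cy5"]
    if n_genes == 0 or hi == 0 or config.n_arrays == 0:
        return pd.DataFrame(columns=cols), pd.DataFrame(columns=["probe_id", "gene_ids"])

    k = rng.integers(lo, hi + 1, size=n_genes)
    gene_of_probe = np.repeat(np.arange(n_genes), k)
    n_probes = len(gene_of_probe)
    probe_id = np.array([f"PB{i:07d}" for i in range(n_probes)])
    affinity = np.exp2(rng.normal(0.0, config.probe_affinity_log2_sd, size=n_probes))
    mrna = truth["mrna_abundance"].to_numpy(dtype=float)
    signal = config.array_signal_scale * mrna[gene_of_probe] * affinity

    a_true = np.log2(np.maximum(signal, 1e-12))
    centered = a_true - a_true.mean()
    bias = config.dye_slope * centered + config.dye_quad * centered**2

    frames = []
    for ai in range(config.n_arrays):
        noise3 = np.exp2(rng.normal(0.0, config.channel_noise_log2_sd, size=n_probes))
        noise5 = np.exp2(rng.normal(0.0, config.channel_noise_log2_sd, size=n_probes))
        bg3 = np.maximum(rng.normal(config.background_mean, config.background_sd, size=n_probes), 0.0)
        bg5 = np.maximum(rng.normal(config.background_mean, config.background_sd, size=n_probes), 0.0)
        fg3 = signal * np.exp2(-bias / 2.0) * noise3 + bg3
        fg5 = signal * np.exp2(+bias / 2.0) * noise5 + bg5
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": probe_id,
                    "array_id": f"A{ai + 1}",
                    "fg_cy3": fg3,
                    "bg_cy3": bg3,
                    "fg_cy5": fg5,
                    "bg_cy5": bg5,
                }
            )
        )
    probes = pd.concat(frames, ignore_index=True)

    unannotated = rng.random(n_probes) < config.frac_unannotated_probes
    gene_ids = np.where(unannotated, "", truth["gene_id"].to_numpy()[gene_of_probe])
    annotation = pd.DataFrame({"probe_id": probe_id, "gene_ids": gene_ids})
    return probes, annotation


def _gene_loci(truth: pd.DataFrame, config: SimConfig, rng: np.random.Generator):
    """Tile every gene on one synthetic chromosome with fixed intergenic gaps.

    Returns (gene table with span coords, exon table). 0-based half-open.
    Loci never overlap by construction.
    """
    n = len(truth)
    e_lo, e_hi = config.exon_length_range
    i_lo, i_hi = config.intron_length_range
    n_exons = rng.integers(1, 4, size=n)
    gene_rows, exon_rows = [], []
    cursor = config.intergenic_gap
    for gi in range(n):
        start = cursor
        pos = start
        for ei in range(n_exons[gi]):
            elen = int(rng.integers(e_lo, e_hi + 1))
            exon_rows.append((truth["gene_id"].iat[gi], pos, pos + elen))
            pos += elen
            if ei < n_exons[gi] - 1:
                pos += int(rng.integers(i_lo, i_hi + 1))
        gene_rows.append((truth["gene_id"].iat[gi], start, pos))
        cursor = pos + config.intergenic_gap
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "start", "end"])
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "start", "end"])
    genes["chrom"] = "chrS"
    exons["chrom"] = "chrS"
    return genes, exons


def simulate_reads(truth: pd.DataFrame, config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read alignments (BED-like) and the matching gene/exon annotation.

    Exonic reads pick a gene multinomially in proportion to mRNA abundance,
    with histone genes down-weighted by ``histone_capture_factor`` (poly-A
    depletion), then an exon in proportion to exon length, landing fully
    inside it. Off-exon reads land fully inside intronic/intergenic
    intervals. Coordinates are 0-based half-open.

    Returns ``(reads, annotation)``: reads with columns ``chrom, start, end,
    read_id, score, strand``; annotation with ``gene_id, chrom, start, end,
    feature, biotype`` rows for genes and exons.
    """
    rng = config.rng("reads")
    n_genes = len(truth)
    read_cols = ["chrom", "start", "end", "read_id", "score", "strand"]
    if n_genes == 0:
        return (pd.DataFrame(columns=read_cols),
                pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "feature", "biotype"]))
    genes, exons = _gene_loci(truth, config, rng)

    n = config.n_reads_total
    rlen = config.read_length
    n_off = int(round(config.frac_off_exon_reads * n))
    n_on = n - n_off

    weights = truth["mrna_abundance"].to_numpy(dtype=float).copy()
    weights[truth["category"].to_numpy() == "histone"] *= config.histone_capture_factor
    if weights.sum() <= 0:
        raise ValueError("no transcriptome to sample reads from: all mRNA abundances are zero")

    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)

    if n_on:
        gene_idx = rng.choice(n_genes, size=n_on, p=weights / weights.sum())
        estart = exons["start"].to_numpy()
        eend = exons["end"].to_numpy()
        # exons were emitted in gene order, so each gene's exons are contiguous
        gid_arr = truth["gene_id"].to_numpy()
        n_ex = exons.groupby("gene_id", sort=False).size().reindex(gid_arr).to_numpy()
        first = np.concatenate([[0], np.cumsum(n_ex)[:-1]])
        max_ex = int(n_ex.max())
        # padded per-gene exon-length matrix -> vectorized length-weighted choice
        lens_mat = np.zeros((n_genes, max_ex))
        for j in range(max_ex):
            has = n_ex > j
            lens_mat[has, j] = (eend - estart)[first[has] + j]
        cum = np.cumsum(lens_mat, axis=1)
        cum /= cum[:, -1:]
        u = rng.random(n_on)
        local = (u[:, None] > cum[gene_idx]).sum(axis=1)
        ei = first[gene_idx] + local
        elen = eend[ei] - estart[ei]
        room = np.maximum(elen - rlen + 1, 1)
        s = estart[ei] + (rng.random(n_on) * room).astype(np.int64)
        e = np.minimum(s + rlen, eend[ei])
        starts[:n_on], ends[:n_on] = s, e
    if n_off:
        # complement of exons (already sorted, non-overlapping by construction)
        es = exons["start"].to_numpy(dtype=np.int64)
        ee = exons["end"].to_numpy(dtype=np.int64)
        gap_start = np.concatenate([[0], ee])
        gap_end = np.concatenate([es, [ee[-1] + config.intergenic_gap]])
        keep = gap_end - gap_start >= rlen
        gaps = np.stack([gap_start[keep], gap_end[keep]], axis=1)
        w = gaps[:, 1] - gaps[:, 0] - rlen + 1
        gi = rng.choice(len(gaps), size=n_off, p=w / w.sum())
        off_start = gaps[gi, 0] + rng.integers(0, w[gi])
        starts[n_on:], ends[n_on:] = off_start, off_start + rlen

    reads = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": starts,
            "end": ends,
            "read_id": [f"R{i:08d}" for i in range(n)],
            "score": 0,
            "strand": "+",
        }
    )

    biotype = truth.set_index("gene_id")["biotype"]
    g = genes.assign(feature="gene", biotype=biotype.loc[genes["gene_id"]].to_numpy())
    e = exons.assign(feature="exon", biotype=biotype.loc[exons["gene_id"]].to_numpy())
    annotation = pd.concat([g, e], ignore_index=True)[
        ["gene_id", "chrom", "start", "end", "feature", "biotype"]
    ]
    return reads, annotation
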