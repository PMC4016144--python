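# Methods

This note documents the models, numerical choices and limitations behind
`triomix`. It describes what the code does and why; every number quoted
here is recomputed by the test suite or by `scripts/acceptance.py`.

## Proteomics: filtering and spectral counting

PSMs arrive with identification probabilities from upstream statistical
validation (e.g. PeptideProphet-style posteriors); the package deliberately
does not re-implement that modeling. Acceptance applies a dual criterion:
probability ≥ `min_probability` (default 0.95) **and** global decoy FDR ≤
`max_fdr` (default 1%). The two are combined as "the smallest threshold
t\* ≥ min_probability at which FDR(t\*) ≤ max_fdr", so both constraints hold
simultaneously; candidate thresholds are `min_probability` itself and every
observed probability above it. The decoy estimator is

FDR(t) = #decoys with p ≥ t / #targets with p ≥ t,

the convention for a concatenated equal-size decoy database (0 when no
target is accepted; an unattainable `max_fdr` is an error naming the best
achievable value). A model-based estimate, mean(1 − p) over accepted
targets, is reported alongside; the two need not agree — the decoy estimate
counts realized decoy matches, the model estimate integrates the posterior.

Spectral counting: each accepted PSM adds one count to **every** protein in
its group, so group-level totals survive the later expansion of protein
groups to genes. `unique_peptides` counts distinct peptide strings whose
group is a single protein (modifications ignored — the input carries plain
sequences). Expansion maps each protein to all its genes, carrying the full
count to each (abundance is not split: downstream statistics are rank-based
and multi-gene rows are flagged and excludable). Proteins without a gene
mapping are tallied, never dropped silently, and so are accepted spectra
whose entire group is unmapped.

## Microarray normalization

Background correction is subtraction floored at 0.5 fluorescence units —
monotone and log-safe; variance-stabilizing alternatives (normexp) are out
of scope. Loess normalization fits a robust locally weighted linear
regression of M on A per array (tricube weights, span 0.3 of the points, 3
robustifying iterations, `delta` = 0.5% of the A-range for fast
interpolation between near-duplicate abscissae) and subtracts the fit; a
zero-spread A degenerates to subtracting the global mean of M. Quantile
normalization replaces the rank-k value of each array with the cross-array
mean of rank-k values; ties receive the mean of the quantile slots they
cover, which makes the operation idempotent to floating tolerance.

The per-gene expression value is the linear-scale intensity `2**A` after
normalization, collapsed by median over a gene's probes within each array
and then averaged across arrays. The collapse rule is configurable
(median/mean/max) because the original analyses rarely state it; the
downstream statistic is rank-based, so any monotone choice gives identical
concordance. Collapsing per array first and averaging after is one of two
defensible orders; averaging channels before collapsing would differ only
through probe-set asymmetries.

## RNA-seq counting

Gene models come from GFF3 (1-based inclusive on disk, converted to 0-based
half-open internally); exons are merged per gene. A read is assigned to a
gene iff it overlaps ≥ 1 base of any exon (`min_overlap` configurable);
reads hitting exons of ≥ 2 genes are ambiguous and counted for none
(conservative and deterministic; no fractional assignment); strand is
ignored (unstranded library chemistry). Overlap resolution uses vectorized
interval joins; a quadratic brute-force oracle pins the semantics in the
tests. A *detected locus* is a gene whose span (first to last exon) is
touched by ≥ 1 read; detected loci with zero exon-overlapping reads are
excluded from quantification and itemized — the class that separates
"transcribed signal somewhere in the locus" from "quantifiable exonic
expression". No RPKM/TPM scaling: a single sample compared by ranks does
not need it.

## Unification and concordance

Identifiers are translated through a pre-resolved mapping table (trailing
`.N` version suffixes stripped). Duplicate (gene, technology) rows
aggregate as sum for spectral counts, median for array intensities, sum for
read counts — configurable, since abundance semantics differ per
technology. The multi-gene flag is the OR over contributing rows and is
monotone under added mappings. Non-coding genes are removed from the
cross-technology comparison (they have no protein side), with the count
reported.

Venn partitioning assigns every detected gene to exactly one of 7 regions;
region summaries are five-number statistics (linear interpolation of order
statistics) of log₂ values, with a 0.5 pseudo-value added to counts only.
Spearman's ρ is the product-moment correlation of midranks (scipy's
implementation behind a thin surface); zero rank variance yields NaN
("undefined"), never 0, because 0 would assert evidence of no association.
The comparison universe defaults to triple-detected genes, the set on which
all three technologies can be compared simultaneously; pairwise co-detection
is available. Exclusion rule sets (all → drop multi-gene → additionally
drop ribosomal/histone/vitellogenin) shrink n monotonically. Category
labels: ribosomal by exact GO term membership (`GO:0005840` in the GO-CC
list), histone and vitellogenin by case-insensitive keyword in the
description, precedence ribosomal > histone > vitellogenin. The keyword
lists and the GO term are parameters. No p-values accompany ρ: with n in
the hundreds they would be uninformatively small, and the analysis is
estimation, not testing.

## The synthetic study

The generator's truth layer draws per-gene (mRNA, protein) abundance from a
Gaussian copula with log-normal marginals (log-mean 2.0, log-sd 2.5 at
study scale); the copula's normal correlation is set to
r = 2·sin(π·ρₛ/6) so the *Spearman* correlation ρₛ (default 0.6) is the
controlled parameter. Category counts follow largest-remainder rounding, so
they are exact and testable. Discordance is built in the direction biology
dictates:

* vitellogenin (0.2% of genes): protein ×100, mRNA ×0.3 — extreme protein
  with present-but-low transcript;
* ribosomal (2%): mRNA ×20 — transcripts over-represented relative to
  protein;
* histone (0.5%): protein ×20, and reads down-weighted ×0.05 *at sampling*
  (poly-A depletion is a library artifact: the truth abundance, and hence
  the array signal, is unchanged);
* non-coding genes (5%): protein ≡ 0.

These magnitudes are free parameters of the generator, documented here and
in `SimConfig`; no study publishes per-category effect sizes, so they were
chosen once to reproduce the *qualitative* structure — a clearly visible
discordant minority whose exclusion, together with multi-gene mappings,
raises ρ substantially.

Raw-data layers: spectra are allocated to proteins multinomially ∝ protein
abundance; 10% of spectra are decoy matches and an equal expected number of
target matches are incorrect (hitting a uniformly random protein), drawn
from the same low-probability Beta(1, 8) mixture with a 10% uniform slab —
the symmetry that makes decoy counting an unbiased FDR estimate, and the
basis of the calibration test. Correct-match probabilities are
1 − Beta(0.5, 25), concentrated near 1, creating the separable threshold
regime of posterior-validated search output. Paralogy is modeled at the
protein level: 8% of proteins share a fixed 30% slice of their peptide
repertoire with a partner (making "has shared spectra" a property of the
protein, not of sampling depth), and 10% of proteins map to 2–4 genes in
the identifier table. Arrays get 2–4 probes per gene with fixed per-probe
affinities, per-channel log-normal noise, an additive background reported
exactly, and an intensity-dependent dye bias (linear + quadratic in
centered A) applied as ±b/2 to the two channels — the curvature the loess
stage must remove; 35% of probes carry no gene annotation. Reads are
placed fully inside exons of genes tiled with fixed gaps on one synthetic
chromosome (single chromosome, 1–3 exons per gene — the simplest layout
that exercises interval overlap); off-exon reads (15%) land in
intronic/intergenic gaps, populating the detected-but-unquantified class.

All outputs are deterministic functions of `SimConfig`: each stage draws
from its own seed stream, so re-running any stage in isolation reproduces
the full-pipeline bytes.

### What the generator does and does not emulate

It reproduces: sparse heavy-tailed proteome detection (~2.5k proteins of
20k genes at default depth, counts spanning 1 to thousands), near-complete
array annotation coverage with a large unannotated-probe bin, the
exon-overlap failure class, decoy/false-target symmetry, and
category-specific discordance. It does not emulate: spectrum-level physics
(ionization bias beyond the histone caricature), probe sequence effects,
positional read bias, multi-mapping reads, batch effects, or biological
replication. Passing tests therefore demonstrate correctness of the
*pipeline computations* under a realistic statistical shape, not that any
particular biological conclusion transfers to real data.

## Parameter recovery and the deep-coverage regime

An analysis-level check feeds simulated raw files through the entire
pipeline and compares the RNA-vs-MS ρ after all exclusions with the
encoded ρₛ = 0.6. Under sparse study-scale defaults this cannot work:
conditioning on detection truncates the abundance distribution and Poisson
counting noise blurs low-count ranks, attenuating the observed ρ to ≈ 0.4 —
a statistical property of shallow sampling, not a pipeline defect. The
`SimConfig.deep_coverage` preset therefore defines the recovery regime:
200 spectra and 240 reads per gene, log-sd 1.0, and low identifier
ambiguity, under which detection is near-complete and the pipeline's ρ
tracks the realized truth correlation to within ≈ 0.014 (residual
attenuation from finite counts), comfortably inside the ±0.05 recovery
band. The replicate study of the exclusion direction (ρ must rise from
rule set *all* to *drop_multi_and_categories*) instead keeps the study-like
ambiguity structure at moderate depth (40 spectra, 80 reads per gene),
where the effect wins in every tested replicate. Problem sizes throughout
(5,000 genes for recovery, 50 replicates, 100-instance oracle sweeps) are
chosen to make the checks statistically meaningful while keeping a full
run in the minutes range on one CPU.

## Degenerate inputs and numerical conventions

Empty PSM tables, zero spectra, zero reads and empty probe tables flow
through with zero counts rather than errors; an all-zero proteome or an
unattainable FDR is an error with a named cause. Duplicate spectrum ids,
duplicate read ids, probabilities outside [0, 1] and inverted intervals are
schema errors naming file, line and column where read from disk. Floating
comparisons in tests use 1e-12 for rank identities and 1e-9 for quantile
idempotence. All randomness flows from numpy `default_rng` seeded via
`SeedSequence`; identical configuration implies byte-identical outputs and
reports (timestamps are confined to stderr logging).

## Known limitations

Single sample per technology (no replicates, no differential analysis);
FDR estimation assumes the equal-size concatenated decoy convention;
the loess stage corrects M but per-gene expression uses A, so residual dye
curvature does not propagate into concordance; ambiguous reads are
discarded rather than rescued by fractional or EM assignment; the unified
table keeps one value per (gene, technology) and is not a general
multi-sample container.
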