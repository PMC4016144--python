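"""The synthetic tri-omics generator: determinism, conservation, structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triomix.simulate import (
    ConfigError,
    SimConfig,
    simulate_array,
    simulate_ground_truth,
    simulate_idmap,
    simulate_psms,
    simulate_reads,
)


class TestConfig:
    def test_invalid_fraction_names_field(self):
        with pytest.raises(ConfigError, match="frac_ribosomal"):
            SimConfig(frac_ribosomal=1.2)

    def test_category_fractions_must_fit(self):
        with pytest.raises(ConfigError, match="category fractions"):
            SimConfig(frac_ribosomal=0.5, frac_noncoding=0.6)

    def test_negative_count_rejected(self):
        with pytest.raises(ConfigError, match="n_spectra_total"):
            SimConfig(n_spectra_total=-1)


class TestGroundTruth:
    def test_zero_genes_gives_empty_table(self):
        assert len(simulate_ground_truth(SimConfig(n_genes=0))) == 0

    def test_exact_category_counts_by_largest_remainder(self):
        truth = simulate_ground_truth(SimConfig(n_genes=1000, frac_ribosomal=0.1, seed=3))
        assert (truth["category"] == "ribosomal").sum() == 100
        assert len(truth) == 1000

    def test_noncoding_genes_have_zero_protein(self, small_truth):
        nc = small_truth[small_truth["biotype"] == "noncoding"]
        assert (nc["protein_abundance"] == 0).all()
        coding = small_truth[small_truth["biotype"] == "protein_coding"]
        assert (coding["protein_abundance"] > 0).all()
        assert (small_truth["mrna_abundance"] > 0).all()

    def test_copula_hits_target_rank_correlation(self):
        cfg = SimConfig(n_genes=5000, protein_rank_corr=0.6, seed=1)
        truth = simulate_ground_truth(cfg)
        reg = truth[(truth["category"] == "regular") & (truth["biotype"] == "protein_coding")]
        rho = stats.spearmanr(reg["mrna_abundance"], reg["protein_abundance"]).statistic
        assert 0.55 <= rho <= 0.65

    def test_category_markers_present(self, small_truth):
        rib = small_truth[small_truth["category"] == "ribosomal"]
        assert rib["go_cc_terms"].str.contains("GO:0005840").all()
        his = small_truth[small_truth["category"] == "histone"]
        assert his["description"].str.lower().str.contains("histone").all()

    def test_deterministic_across_calls(self, small_config):
        a = simulate_ground_truth(small_config)
        b = simulate_ground_truth(small_config)
        pd.testing.assert_frame_equal(a, b)


class TestPsmSimulation:
    def test_zero_spectra_empty_table(self, small_truth, small_config):
        cfg = SimConfig(n_spectra_total=0)
        assert len(simulate_psms(small_truth, cfg)) == 0

    def test_row_conservation(self, small_truth, small_config):
        psms = simulate_psms(small_truth, small_config)
        assert len(psms) == small_config.n_spectra_total
        assert psms["spectrum_id"].is_unique

    def test_decoy_count_within_binomial_99_interval(self, small_truth):
        cfg = SimConfig(n_spectra_total=1000, decoy_fraction=0.5, seed=5)
        psms = simulate_psms(small_truth, cfg)
        n_decoy = psms["is_decoy"].sum()
        lo, hi = stats.binom.interval(0.99, 1000, 0.5)
        assert lo <= n_decoy <= hi

    def test_all_abundance_on_one_gene(self):
        truth = simulate_ground_truth(SimConfig(n_genes=5, frac_noncoding=0, seed=2)).copy()
        truth["protein_abundance"] = [0.0, 0.0, 10.0, 0.0, 0.0]
        cfg = SimConfig(n_spectra_total=200, decoy_fraction=0.0, false_target_fraction=0.0,
                        frac_shared_proteins=0.0, seed=2)
        psms = simulate_psms(truth, cfg)
        target_gene = truth.loc[truth["protein_abundance"] > 0, "gene_id"].iloc[0]
        assert psms["proteins"].eq(f"PRO_{target_gene}").all()

    def test_zero_proteome_is_an_error(self, small_truth):
        truth = small_truth.copy()
        truth["protein_abundance"] = 0.0
        with pytest.raises(ValueError, match="no detectable proteome"):
            simulate_psms(truth, SimConfig(n_spectra_total=10))

    def test_decoy_records_marked_and_low_probability(self, small_truth, small_config):
        psms = simulate_psms(small_truth, small_config)
        decoys = psms[psms["is_decoy"] == 1]
        targets = psms[psms["is_decoy"] == 0]
        assert decoys["proteins"].str.startswith("DECOY_").all()
        assert decoys["probability"].median() < targets["probability"].median()


class TestArraySimulation:
    def test_probe_row_conservation(self, small_truth):
        cfg = SimConfig(probes_per_gene_range=(3, 3), n_arrays=2, seed=4)
        probes, annotation = simulate_array(small_truth.head(10), cfg)
        assert len(annotation) == 30
        assert len(probes) == 30 * 2

    def test_noise_free_symmetric_channels_give_zero_m(self, small_truth):
        cfg = SimConfig(
            channel_noise_log2_sd=0.0, dye_slope=0.0, dye_quad=0.0, seed=4
        )
        probes, _ = simulate_array(small_truth.head(20), cfg)
        m = np.log2(probes["fg_cy5"] - probes["bg_cy5"]) - np.log2(probes["fg_cy3"] - probes["bg_cy3"])
        assert np.allclose(m, 0.0, atol=1e-9)

    def test_dye_slope_sign_shows_in_extreme_a_deciles(self, small_truth):
        cfg = SimConfig(dye_slope=0.6, dye_quad=0.0, channel_noise_log2_sd=0.05, seed=4)
        probes, _ = simulate_array(small_truth, cfg)
        cy3 = np.maximum(probes["fg_cy3"] - probes["bg_cy3"], 0.5)
        cy5 = np.maximum(probes["fg_cy5"] - probes["bg_cy5"], 0.5)
        m = np.log2(cy5 / cy3)
        a = 0.5 * np.log2(cy5 * cy3)
        lo, hi = np.quantile(a, [0.1, 0.9])
        assert m[a >= hi].mean() - m[a <= lo].mean() > 0

    def test_unannotated_fraction_roughly_respected(self, small_truth):
        cfg = SimConfig(frac_unannotated_probes=0.4, seed=4)
        _, annotation = simulate_array(small_truth, cfg)
        frac = annotation["gene_ids"].eq("").mean()
        assert 0.3 < frac < 0.5


class TestReadSimulation:
    def test_read_row_conservation(self, small_truth, small_config):
        reads, _ = simulate_reads(small_truth, small_config)
        assert len(reads) == small_config.n_reads_total

    def test_all_off_exon_means_no_exon_overlap(self, small_truth):
        from triomix.rnaseq import count_reads_per_gene, gene_models_from_annotation

        cfg = SimConfig(n_reads_total=2000, frac_off_exon_reads=1.0, seed=6)
        reads, annotation = simulate_reads(small_truth.head(30), cfg)
        res = count_reads_per_gene(reads, gene_models_from_annotation(annotation))
        assert res.n_assigned == 0 and res.n_ambiguous == 0

    def test_zero_off_exon_single_gene_lands_in_exons(self, small_truth):
        from triomix.rnaseq import count_reads_per_gene, gene_models_from_annotation

        cfg = SimConfig(n_reads_total=500, frac_off_exon_reads=0.0, seed=6)
        reads, annotation = simulate_reads(small_truth.head(1), cfg)
        res = count_reads_per_gene(reads, gene_models_from_annotation(annotation))
        assert res.n_assigned == 500

    def test_gene_loci_never_overlap(self, small_truth, small_config):
        _, annotation = simulate_reads(small_truth, small_config)
        genes = annotation[annotation["feature"] == "gene"].sort_values("start")
        assert (genes["start"].to_numpy()[1:] >= genes["end"].to_numpy()[:-1]).all()

    def test_histone_depletion_reduces_read_share(self):
        from triomix.rnaseq import count_reads_per_gene, gene_models_from_annotation

        cfg = SimConfig(
            n_genes=400, frac_histone=0.1, histone_capture_factor=0.01,
            n_reads_total=100000, frac_off_exon_reads=0.0, seed=7,
        )
        truth = simulate_ground_truth(cfg)
        reads, annotation = simulate_reads(truth, cfg)
        res = count_reads_per_gene(reads, gene_models_from_annotation(annotation))
        counts = res.counts.set_index("gene_id")["count"]
        his = truth["category"] == "histone"
        share_reads = counts[truth.loc[his, "gene_id"]].sum() / counts.sum()
        share_mrna = truth.loc[his, "mrna_abundance"].sum() / truth["mrna_abundance"].sum()
        assert share_reads < 0.1 * share_mrna


class TestIdmap:
    def test_only_coding_genes_get_proteins(self, small_truth, small_config):
        idmap = simulate_idmap(small_truth, small_config)
        coding = set(small_truth.loc[small_truth["biotype"] == "protein_coding", "gene_id"])
        assert len(idmap) == len(coding)
        assert idmap["entity_type"].eq("protein").all()

    def test_determinism_is_byte_identical(self, small_truth, small_config):
        a = simulate_idmap(small_truth, small_config)
        b = simulate_idmap(small_truth, small_config)
        assert a.to_csv() == b.to_csv()
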