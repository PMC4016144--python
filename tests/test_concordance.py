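"""Venn partition, region summaries, category labels and Spearman concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from triomix.concordance import (
    REGIONS,
    annotate_categories,
    concordance_with_exclusions,
    five_number,
    region_summaries,
    spearman,
    venn_partition,
)


class TestVennPartition:
    def test_enumerable_example(self):
        part = venn_partition(
            {"proteomics": {"1", "2", "3"}, "rnaseq": {"2", "3", "4"}, "array": {"3", "5"}}
        )
        assert part.region_of["3"] == "MS∩RNA∩ARR"
        assert part.region_of["2"] == "MS∩RNA"
        assert part.region_of["1"] == "MS-only"
        assert part.region_of["4"] == "RNA-only"
        assert part.region_of["5"] == "ARR-only"
        assert sum(part.region_sizes.values()) == 5 == part.union_size

    def test_identical_sets_all_triple(self):
        s = {"a", "b"}
        part = venn_partition({"proteomics": s, "rnaseq": s, "array": s})
        assert part.region_sizes["MS∩RNA∩ARR"] == 2
        assert sum(v for k, v in part.region_sizes.items() if k != "MS∩RNA∩ARR") == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_sizes_match_brute_force_membership(self, seed):
        rng = np.random.default_rng(900 + seed)
        ids = np.arange(10000)
        sets = {
            t: set(map(int, ids[rng.random(len(ids)) < p]))
            for t, p in (("proteomics", 0.2), ("rnaseq", 0.6), ("array", 0.5))
        }
        part = venn_partition(sets)
        ms, rna, arr = sets["proteomics"], sets["rnaseq"], sets["array"]
        expect = {
            "MS∩RNA∩ARR": len(ms & rna & arr),
            "MS∩RNA": len((ms & rna) - arr),
            "MS∩ARR": len((ms & arr) - rna),
            "RNA∩ARR": len((rna & arr) - ms),
            "MS-only": len(ms - rna - arr),
            "RNA-only": len(rna - ms - arr),
            "ARR-only": len(arr - ms - rna),
        }
        assert part.region_sizes == expect
        assert part.union_size == len(ms | rna | arr)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        ms=st.sets(st.integers(0, 50)),
        rna=st.sets(st.integers(0, 50)),
        arr=st.sets(st.integers(0, 50)),
    )
    def test_partition_is_complete_and_disjoint(self, ms, rna, arr):
        part = venn_partition({"proteomics": ms, "rnaseq": rna, "array": arr})
        assert set(part.region_of) == (ms | rna | arr)
        assert sum(part.region_sizes.values()) == len(ms | rna | arr)


class TestRegionSummaries:
    def test_five_number_of_small_vector(self):
        fn = five_number(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert (fn["q1"], fn["median"], fn["q3"]) == (2.0, 3.0, 4.0)
        assert (fn["min"], fn["max"]) == (1.0, 5.0)

    def test_single_value_collapses(self):
        fn = five_number(np.array([7.0]))
        assert len(set(fn.values())) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sort_oracle(self, seed):
        rng = np.random.default_rng(1100 + seed)
        v = rng.uniform(0, 100, 101)
        fn = five_number(v)
        s = np.sort(v)
        # linear interpolation of order statistics at h = (n-1)q
        for q, key in ((0.25, "q1"), (0.5, "median"), (0.75, "q3")):
            h = (len(s) - 1) * q
            lo = int(np.floor(h))
            expect = s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])
            assert fn[key] == pytest.approx(expect)

    def test_summaries_grouped_by_region_and_technology(self):
        unified = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "proteomics_value": [4.0, np.nan, 8.0],
                "rnaseq_value": [10.0, 20.0, np.nan],
                "array_value": [np.nan, np.nan, np.nan],
                "proteomics_detected": [True, False, True],
                "rnaseq_detected": [True, True, False],
                "array_detected": [False, False, False],
                "multi_gene": False,
                "biotype": "protein_coding",
            }
        )
        part = venn_partition({"proteomics": {"a", "c"}, "rnaseq": {"a", "b"}, "array": set()})
        out = region_summaries(part, unified)
        ms_rna = out[(out["region"] == "MS∩RNA") & (out["technology"] == "proteomics")]
        assert ms_rna["n"].iloc[0] == 1
        assert ms_rna["median"].iloc[0] == pytest.approx(np.log2(4.5))
        assert not ((out["region"] == "ARR-only").any())


class TestAnnotateCategories:
    def info(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "description", "go_cc_terms"]
        ).set_index("gene_id")

    def test_keyword_and_go_rules(self):
        info = self.info(
            [
                ("g1", "vitellogenin 2 precursor", ""),
                ("g2", "Histone H2A", ""),
                ("g3", "60S ribosomal protein", "GO:0005840;GO:0005737"),
                ("g4", "", ""),
            ]
        )
        lab = annotate_categories(info)
        assert lab["g1"] == "vitellogenin"
        assert lab["g2"] == "histone"
        assert lab["g3"] == "ribosomal"
        assert lab["g4"] == "none"

    def test_ribosomal_precedence_over_keywords(self):
        info = self.info([("g1", "histone-like protein", "GO:0005840")])
        assert annotate_categories(info)["g1"] == "ribosomal"

    def test_go_substring_does_not_count(self):
        # the term must match exactly within the term list, not as a substring
        info = self.info([("g1", "protein x", "GO:00058401")])
        assert annotate_categories(info)["g1"] == "none"


class TestSpearman:
    def test_tie_free_closed_form_example(self):
        assert spearman([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6, abs=1e-12)

    def test_monotone_transform_invariance(self):
        x = np.array([1.0, 5.0, 2.0, 9.0, 4.0])
        assert spearman(x, np.exp(x)) == pytest.approx(1.0, abs=1e-12)

    def test_midrank_tie_example(self):
        # hand-computed product-moment correlation of midranks
        assert spearman([1, 2, 2, 3], [1, 2, 3, 4]) == pytest.approx(0.9486832980505138, abs=1e-9)

    def test_zero_rank_variance_is_undefined_not_zero(self):
        assert np.isnan(spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            spearman([1, 2], [3, 4])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(-100, 100), st.integers(-100, 100)), min_size=3, max_size=60
        )
    )
    def test_symmetry_and_closed_form_on_tie_free_data(self, pairs):
        x = np.array([p[0] for p in pairs], dtype=float)
        y = np.array([p[1] for p in pairs], dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            assert np.isnan(spearman(x, y))
            return
        assert spearman(x, y) == pytest.approx(spearman(y, x), abs=1e-12)
        if len(set(x)) == len(x) and len(set(y)) == len(y):
            n = len(x)
            d = np.argsort(np.argsort(x)) - np.argsort(np.argsort(y))
            closed = 1 - 6 * float((d**2).sum()) / (n * (n**2 - 1))
            assert spearman(x, y) == pytest.approx(closed, abs=1e-12)


class TestConcordanceWithExclusions:
    def unified(self, n=40, rng=None, multi=None, extra=None):
        rng = rng or np.random.default_rng(0)
        x = rng.uniform(1, 100, n)
        df = pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(n)],
                "biotype": "protein_coding",
                "proteomics_value": x + rng.normal(0, 5, n),
                "rnaseq_value": x,
                "array_value": x * 2,
                "proteomics_detected": True,
                "rnaseq_detected": True,
                "array_detected": True,
                "multi_gene": multi if multi is not None else False,
            }
        )
        if extra is not None:
            df = pd.concat([df, extra], ignore_index=True)
        return df

    def categories(self, unified, labels=None):
        info = pd.DataFrame(
            {
                "gene_id": unified["gene_id"],
                "description": "",
                "go_cc_terms": "",
            }
        ).set_index("gene_id")
        ser = annotate_categories(info)
        if labels:
            for g, lab in labels.items():
                ser[g] = lab
        return ser

    def test_rule_sets_coincide_without_flags_or_categories(self):
        u = self.unified()
        res = concordance_with_exclusions(u, self.categories(u))
        by_rule = {(r.pair, r.rule_set): r for r in res}
        for pair in {r.pair for r in res}:
            a = by_rule[(pair, "all")]
            c = by_rule[(pair, "drop_multi_and_categories")]
            assert a.rho == pytest.approx(c.rho)
            assert a.n == c.n

    def test_discordant_category_exclusion_raises_rho(self):
        rng = np.random.default_rng(4)
        # 8 vitellogenin-like genes: protein very high, transcript very low
        extra = pd.DataFrame(
            {
                "gene_id": [f"V{i}" for i in range(8)],
                "biotype": "protein_coding",
                "proteomics_value": rng.uniform(400, 600, 8),
                "rnaseq_value": rng.uniform(0.5, 2, 8),
                "array_value": rng.uniform(1, 4, 8),
                "proteomics_detected": True,
                "rnaseq_detected": True,
                "array_detected": True,
                "multi_gene": False,
            }
        )
        u = self.unified(extra=extra)
        cats = self.categories(u, labels={f"V{i}": "vitellogenin" for i in range(8)})
        res = {
            (r.pair, r.rule_set): r.rho
            for r in concordance_with_exclusions(u, cats)
        }
        pair = ("proteomics", "rnaseq")
        assert res[(pair, "drop_multi_and_categories")] > res[(pair, "all")]

    def test_n_monotone_across_rule_sets(self):
        rng = np.random.default_rng(5)
        u = self.unified(n=60, rng=rng, multi=rng.random(60) < 0.3)
        cats = self.categories(u, labels={"G0": "ribosomal", "G1": "histone"})
        for pair in (("proteomics", "rnaseq"), ("proteomics", "array"), ("rnaseq", "array")):
            ns = [r.n for r in concordance_with_exclusions(u, cats) if r.pair == pair]
            assert ns == sorted(ns, reverse=True)

    def test_low_n_flagged(self):
        u = self.unified(n=5)
        res = concordance_with_exclusions(u, self.categories(u))
        assert all(r.low_n for r in res)

    def test_pairwise_universe_uses_codetection(self):
        u = self.unified(n=20)
        u.loc[10:, "array_detected"] = False
        u.loc[10:, "array_value"] = np.nan
        res = concordance_with_exclusions(u, self.categories(u), universe="pairwise")
        by = {(r.pair, r.rule_set): r for r in res}
        assert by[(("proteomics", "rnaseq"), "all")].n == 20
        assert by[(("proteomics", "array"), "all")].n == 10
        res_t = concordance_with_exclusions(u, self.categories(u), universe="triple")
        by_t = {(r.pair, r.rule_set): r for r in res_t}
        assert by_t[(("proteomics", "rnaseq"), "all")].n == 10
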