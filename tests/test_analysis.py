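"""Binomial test against an exact rational-arithmetic oracle, confidence
intervals, aggregation and the three-way classification."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poe_placenta.analysis import (
    ExpressedParent,
    LocusClass,
    aggregate_gene,
    binomial_test_two_sided,
    bonferroni,
    class_summary,
    classify_gene,
    filter_snp_by_coverage,
    group_breakdown,
    map_counts_to_parents,
    proportion_ci,
)
from poe_placenta.config import CohortConfig, TrioFamily


def exact_two_sided_p(k: int, n: int) -> float:
    """Oracle: exact rational sum of all outcome probabilities at most as
    likely as the observed one, for the symmetric null p = 0.5."""
    pmf = [Fraction(comb(n, i), 2**n) for i in range(n + 1)]
    observed = pmf[k]
    return float(sum(p for p in pmf if p <= observed))


class TestBinomialTest:
    def test_modal_outcome_gives_p_one(self):
        for n in (2, 10, 100):
            assert binomial_test_two_sided(n // 2, n) == pytest.approx(1.0)

    def test_small_count_example(self):
        # brute-force sum over i <= 5 and i >= 24 of C(29, i) / 2^29
        assert binomial_test_two_sided(5, 29) == pytest.approx(5.4611e-4, rel=1e-4)

    def test_closed_form_extreme(self):
        assert binomial_test_two_sided(0, 10) == pytest.approx(2 * 2**-10)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.integers(min_value=1, max_value=200), st.data())
    def test_agrees_with_exact_enumeration(self, n, data):
        k = data.draw(st.integers(min_value=0, max_value=n))
        expected = exact_two_sided_p(k, n)
        assert binomial_test_two_sided(k, n) == pytest.approx(expected, rel=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_test_two_sided(1, 0)
        with pytest.raises(ValueError):
            binomial_test_two_sided(5, 3)


class TestBonferroni:
    def test_scaling_and_cap(self):
        assert bonferroni(1e-4, 91) == pytest.approx(9.1e-3)
        assert bonferroni(0.5, 91) == 1.0

    def test_borderline_chain(self):
        # 5.4612e-4 * 91 lands just under the 0.05 significance level
        p_corr = bonferroni(binomial_test_two_sided(5, 29), 91)
        assert 0.049 < p_corr < 0.05


class TestProportionCi:
    def test_k_equals_n_hits_upper_boundary(self):
        for method in ("clopper_pearson", "wilson"):
            _, high = proportion_ci(10, 10, method=method)
            assert high == pytest.approx(1.0)

    def test_clopper_pearson_zero_successes_closed_form(self):
        low, high = proportion_ci(0, 10, method="clopper_pearson")
        assert low == 0.0
        assert high == pytest.approx(1 - 0.025 ** (1 / 10), rel=1e-6)

    def test_point_estimate_contained(self):
        low, high = proportion_ci(687, 722)
        assert low <= 687 / 722 <= high

    def test_bootstrap_over_families(self):
        fam = pd.DataFrame(
            {
                "family_id": ["F1", "F1", "F2", "F3", "F4", "F5"],
                "mat_reads": [40, 30, 55, 60, 45, 52],
                "pat_reads": [10, 15, 12, 8, 9, 11],
            }
        )
        k = int(fam["mat_reads"].sum())
        n = int((fam["mat_reads"] + fam["pat_reads"]).sum())
        low, high = proportion_ci(
            k, n, method="bootstrap", family_counts=fam, n_boot=500, seed=3
        )
        assert 0 < low <= k / n <= high < 1

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown CI method"):
            proportion_ci(1, 2, method="jackknife")


class TestCountsAndAggregation:
    def test_parental_label_mapping_and_symmetry(self):
        assert map_counts_to_parents(687, 35, "ref", "alt") == (687, 35)
        assert map_counts_to_parents(687, 35, "alt", "ref") == (35, 687)
        assert map_counts_to_parents(0, 0, "ref", "alt") == (0, 0)

    def test_coverage_median_boundary(self):
        counts = pd.DataFrame(
            {
                "family_id": ["F1", "F2", "F3"] * 2,
                "snp_id": ["s_pass"] * 3 + ["s_fail"] * 3,
                "gene_id": ["g"] * 6,
                "mat_reads": [2, 2, 2, 0, 1, 1],
                "pat_reads": [1, 1, 1, 0, 0, 1],
            }
        )
        passing = filter_snp_by_coverage(counts, 3)
        # medians: s_pass {3,3,3} -> 3 passes; s_fail {0,1,2} -> 1 fails
        assert list(passing) == ["s_pass"]

    def test_gene_sums_over_families_and_snps(self):
        counts = pd.DataFrame(
            {
                "family_id": ["F1", "F2", "F3", "F1", "F1"],
                "snp_id": ["s1", "s1", "s1", "s2", "s3"],
                "gene_id": ["g1", "g1", "g1", "g2", "g2"],
                "mat_reads": [10, 8, 9, 5, 5],
                "pat_reads": [0, 1, 0, 5, 5],
            }
        )
        agg = aggregate_gene(counts).set_index("gene_id")
        assert (agg.loc["g1", "mat_total"], agg.loc["g1", "pat_total"]) == (27, 1)
        assert (agg.loc["g2", "mat_total"], agg.loc["g2", "pat_total"]) == (10, 10)
        assert agg.loc["g2", "n_informative_families"] == 1


class TestClassification:
    def setup_method(self):
        self.config = CohortConfig(n_tests_bonferroni=91)

    def _classify_counts(self, mat, pat):
        n = mat + pat
        p_corr = bonferroni(binomial_test_two_sided(mat, n), 91)
        return classify_gene(mat / n, p_corr, self.config)

    def test_strong_paternal_monoallelic(self):
        cls, parent = self._classify_counts(13, 6101)
        assert (cls, parent) == (LocusClass.IMPRINTED, ExpressedParent.PAT)

    def test_maternal_bias(self):
        cls, parent = self._classify_counts(248, 83)
        assert (cls, parent) == (LocusClass.BIASED, ExpressedParent.MAT)

    def test_balanced_counts_are_biallelic(self):
        cls, parent = self._classify_counts(50, 50)
        assert (cls, parent) == (LocusClass.BIALLELIC, ExpressedParent.BOTH)

    def test_significance_gates_extreme_fraction(self):
        # skewed fraction but non-significant corrected p: still biallelic
        cls, _ = classify_gene(0.95, 0.2, self.config)
        assert cls == LocusClass.BIALLELIC

    def test_boundary_fraction_at_imprinted_threshold_is_biased(self):
        cls, _ = classify_gene(0.90, 1e-10, self.config)
        assert cls == LocusClass.BIASED

    def test_classes_partition_all_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            prop = rng.uniform(0, 1)
            p_corr = rng.uniform(0, 1)
            cls, _ = classify_gene(prop, p_corr, self.config)
            assert cls in (LocusClass.IMPRINTED, LocusClass.BIASED, LocusClass.BIALLELIC)


class TestSummaries:
    def test_single_gene_class_median_is_its_value(self):
        summaries = pd.DataFrame(
            {
                "gene_id": ["g1"],
                "locus_class": ["imprinted"],
                "expressed_parent": ["Mat"],
                "preferred_fraction": [0.97],
            }
        )
        cs = class_summary(summaries)
        row = cs[(cs["locus_class"] == "imprinted") & (cs["expressed_parent"] == "all")]
        assert row["median_preferred_fraction"].iloc[0] == pytest.approx(0.97)

    def test_group_breakdown_conserves_totals_and_marks_empty(self):
        families = [
            TrioFamily("F1", "P1", "M1", "D1", "PE", 270),
            TrioFamily("F2", "P2", "M2", None, "trim1", 60),
        ]
        counts = pd.DataFrame(
            {
                "family_id": ["F1", "F2"],
                "snp_id": ["s1", "s1"],
                "gene_id": ["g1", "g1"],
                "mat_reads": [30, 20],
                "pat_reads": [10, 20],
            }
        )
        groups = group_breakdown(counts, families, CohortConfig())
        by_group = groups.set_index("clinical_group")
        assert groups["mat_reads"].sum() == 50 and groups["pat_reads"].sum() == 30
        assert by_group.loc["PE", "mat_proportion"] == pytest.approx(0.75)
        # groups without informative reads are empty, not zero-proportion
        assert np.isnan(by_group.loc["GD", "mat_proportion"])
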