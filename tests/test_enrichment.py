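"""Chi-squared tail enrichment, SUMSTAT and Bonferroni thresholds."""

import numpy as np
import pytest

from sweepset.enrichment import (
    binomial_cross_check,
    bonferroni_threshold,
    sumstat,
    sumstat_significance,
    tail_enrichment,
)


class TestTailEnrichment:
    def test_observed_equals_expected_is_null(self):
        res = tail_enrichment(50, 1000, 0.05)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert res.percent_excess == pytest.approx(0.0)

    def test_worked_excess_example(self):
        # O=75, T=1000, alpha=0.05: chi2 = 12.5 + 625/950
        res = tail_enrichment(75, 1000, 0.05)
        assert res.chi2 == pytest.approx(12.5 + 625 / 950, abs=1e-9)
        assert res.p == pytest.approx(2.87e-4, rel=0.01)
        assert res.direction == "excess"
        assert res.percent_excess == pytest.approx(50.0)

    def test_total_deficit_example(self):
        res = tail_enrichment(0, 1000, 0.05)
        assert res.chi2 == pytest.approx(50 + 2500 / 950, abs=1e-9)
        assert res.direction == "deficit"

    def test_agrees_with_exact_binomial_within_factor_two(self):
        # moderate deviations (within ~3 sigma), where the 1-df chi-squared
        # normal approximation is meaningful
        for o, t in [(60, 1000), (40, 1000), (65, 1000), (92, 1500)]:
            res = tail_enrichment(o, t, 0.05)
            exact = binomial_cross_check(o, t, 0.05)
            if exact > 0:
                assert 0.5 < res.p / exact < 2.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            tail_enrichment(0, 0, 0.05)
        with pytest.raises(ValueError):
            tail_enrichment(10, 5, 0.05)
        with pytest.warns(UserWarning):  # expected count below 5
            tail_enrichment(1, 20, 0.05)


class TestSumstat:
    def test_sum_of_per_gene_minima(self):
        res = sumstat(
            {"g1": [0.2, 0.05], "g2": [0.5], "g3": [0.01, 0.9]}, label="zinc"
        )
        assert res.value == pytest.approx(0.56)
        assert res.n_genes_used == 3

    def test_all_minima_one_gives_set_size(self):
        res = sumstat({f"g{i}": [1.0, 1.0] for i in range(7)})
        assert res.value == pytest.approx(7.0)

    def test_invariant_to_snp_order_within_genes(self):
        rng = np.random.default_rng(0)
        pv = {f"g{i}": rng.uniform(size=9) for i in range(5)}
        shuffled = {k: rng.permutation(v) for k, v in pv.items()}
        assert sumstat(pv).value == pytest.approx(sumstat(shuffled).value)

    def test_gene_without_snps_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            res = sumstat({"g1": [0.3], "g2": []})
        assert res.n_genes_used == 1 and res.n_genes_dropped == 1

    def test_adding_gene_with_min_one_adds_exactly_one(self):
        base = {"g1": [0.2], "g2": [0.4]}
        extended = dict(base, g3=[1.0])
        assert sumstat(extended).value == pytest.approx(sumstat(base).value + 1.0)


class TestSumstatSignificance:
    def test_value_below_all_nulls_gets_pseudocount_p(self):
        nulls = np.linspace(1, 2, 1000)
        res = sumstat_significance(0.5, nulls)
        assert res.empirical_p == pytest.approx(1 / 1001)

    def test_median_value_is_about_half(self):
        nulls = np.linspace(0, 1, 999)
        res = sumstat_significance(float(np.median(nulls)), nulls)
        assert res.empirical_p == pytest.approx(0.5, abs=0.01)

    def test_tier_flags_nested(self):
        nulls = np.linspace(1, 2, 1000)
        res = sumstat_significance(0.5, nulls)
        tiers = [res.tiers[t] for t in sorted(res.tiers, reverse=True)]
        assert tiers == sorted(tiers, reverse=True)  # 5% tier implies none below

    def test_short_null_rejected_unless_forced(self):
        with pytest.raises(ValueError):
            sumstat_significance(1.0, np.arange(50))
        res = sumstat_significance(1.0, np.arange(50), force=True)
        assert res.empirical_p is not None


class TestBonferroni:
    def test_gene_level_threshold(self):
        # 269 genes x 40 populations
        _, rounded = bonferroni_threshold(269 * 40)
        assert rounded == pytest.approx(4.65e-6)

    def test_set_level_threshold(self):
        # 13 micronutrients x 40 populations
        _, rounded = bonferroni_threshold(13 * 40)
        assert rounded == pytest.approx(9.62e-5)

    def test_single_test_is_alpha(self):
        full, rounded = bonferroni_threshold(1)
        assert full == rounded == pytest.approx(0.05)
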