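"""Per-site Weir-Cockerham FST against an independently coded oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sweepset.fst import weir_cockerham_fst, weir_cockerham_theta, pairwise_scan
from sweepset.variant_io import GenotypeTable

from conftest import wc_theta_oracle


def _dosage(counts: dict[int, int]) -> np.ndarray:
    out = []
    for dos, n in counts.items():
        out.extend([dos] * n)
    return np.array(out)


class TestSingleSite:
    def test_fixed_difference_is_one(self):
        rec = weir_cockerham_fst(np.zeros(25, int), np.full(25, 2))
        assert rec.theta == pytest.approx(1.0)

    def test_identical_configurations_not_positive(self):
        g = _dosage({0: 3, 1: 2, 2: 1})
        rec = weir_cockerham_fst(g, g.copy())
        assert rec.defined and rec.theta <= 0.0

    def test_worked_example_matches_frozen_oracle_value(self):
        # popA {0/0:2, 0/1:2, 1/1:1}, popB {0/0:4, 0/1:1}:
        # a=0.0225, b=0.0375, c=0.15 -> theta = 0.0225/0.21
        ga = _dosage({0: 2, 1: 2, 2: 1})
        gb = _dosage({0: 4, 1: 1})
        rec = weir_cockerham_fst(ga, gb)
        assert rec.theta == pytest.approx(0.0225 / 0.21, abs=1e-12)
        assert rec.theta == pytest.approx(wc_theta_oracle(list(ga), list(gb)),
                                          abs=1e-12)

    def test_monomorphic_in_both_is_undefined_not_zero(self):
        rec = weir_cockerham_fst(np.zeros(10, int), np.zeros(7, int))
        assert not rec.defined

    def test_all_missing_population_is_undefined(self):
        rec = weir_cockerham_fst(np.full(5, -1), _dosage({0: 3, 1: 2}))
        assert not rec.defined

    def test_missing_genotypes_excluded_from_counts(self):
        ga = np.array([0, 1, 2, -1, -1])
        gb = np.array([0, 0, 1, 1, -1])
        rec = weir_cockerham_fst(ga, gb)
        assert (rec.n_a, rec.n_b) == (3, 4)
        assert rec.theta == pytest.approx(
            wc_theta_oracle([0, 1, 2], [0, 0, 1, 1]), abs=1e-12
        )


def test_thousand_random_sites_match_oracle_to_six_decimals():
    """The vectorized estimator equals the scalar component equations."""
    rng = np.random.default_rng(42)
    n_sites = 1000
    na, nb = 12, 9
    da = rng.choice([0, 1, 2, -1], size=(na, n_sites), p=[0.4, 0.3, 0.2, 0.1])
    db = rng.choice([0, 1, 2, -1], size=(nb, n_sites), p=[0.5, 0.2, 0.2, 0.1])
    theta, _, _ = weir_cockerham_theta(da, db)
    for j in range(n_sites):
        expect = wc_theta_oracle(
            [int(x) for x in da[:, j] if x >= 0],
            [int(x) for x in db[:, j] if x >= 0],
        )
        if np.isnan(expect):
            assert np.isnan(theta[j])
        else:
            assert theta[j] == pytest.approx(expect, abs=1e-6)


@given(
    st.lists(st.integers(0, 2), min_size=2, max_size=20),
    st.lists(st.integers(0, 2), min_size=2, max_size=20),
)
def test_theta_invariant_under_allele_label_swap(ga, gb):
    a, b = np.array(ga), np.array(gb)
    rec = weir_cockerham_fst(a, b)
    rec_flip = weir_cockerham_fst(2 - a, 2 - b)
    if rec.defined:
        assert rec_flip.theta == pytest.approx(rec.theta, abs=1e-12)
        assert rec.theta <= 1.0
    else:
        assert not rec_flip.defined


def _toy_table(rng, n_pops=3, n_snps=40, n_per_pop=8):
    pops = ["AFR", "EUR", "EAS"][:n_pops]
    samples, labels = [], []
    for p in pops:
        for i in range(n_per_pop):
            samples.append(f"{p}_{i}")
            labels.append(p)
    dosage = rng.integers(0, 3, size=(n_snps, len(samples))).astype(np.int8)
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n_snps + 1) * 100,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeTable(
        variants=variants,
        dosage=dosage,
        samples=samples,
        sample_pops=pd.Series(labels, index=samples),
    )


class TestPairwiseScan:
    def test_one_channel_per_test_population(self):
        table = _toy_table(np.random.default_rng(1))
        out = pairwise_scan(table, "AFR")
        assert sorted(out["channel"].unique()) == ["fst:AFR:EAS", "fst:AFR:EUR"]

    def test_channel_values_match_single_site_calls(self):
        table = _toy_table(np.random.default_rng(2))
        out = pairwise_scan(table, "AFR", ["EUR"])
        da = table.population_dosage("AFR")
        db = table.population_dosage("EUR")
        for j, row in enumerate(out.itertuples()):
            rec = weir_cockerham_fst(da[j], db[j])
            if np.isnan(rec.theta):
                assert np.isnan(row.value)
            else:
                assert row.value == pytest.approx(rec.theta, abs=1e-12)

    def test_reference_against_itself_never_positive(self):
        table = _toy_table(np.random.default_rng(3))
        out = pairwise_scan(table, "AFR", ["AFR"])
        vals = out["value"].to_numpy()
        assert np.all(np.isnan(vals) | (vals <= 1e-12))

    def test_unknown_population_errors(self):
        table = _toy_table(np.random.default_rng(4))
        with pytest.raises(KeyError):
            pairwise_scan(table, "YRI")
        with pytest.raises(KeyError):
            pairwise_scan(table, "AFR", ["XXX"])
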