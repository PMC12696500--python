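"""Empirical-tail ranking, tier classification and gene slicing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sweepset.empirical import (
    classify,
    empirical_p,
    empirical_p_of,
    gene_snp_slice,
)


class TestEmpiricalP:
    def test_top_score_gets_one_over_n(self):
        rng = np.random.default_rng(0)
        v = rng.permutation(np.arange(10_000, dtype=float))
        p = empirical_p(v)
        assert p[np.argmax(v)] == pytest.approx(1e-4)
        assert p[np.argmin(v)] == pytest.approx(1.0)

    def test_all_identical_scores_share_p_one(self):
        p = empirical_p(np.full(50, 3.3))
        assert np.all(p == 1.0)

    def test_ties_at_top_share_rank(self):
        v = np.array([5.0, 5.0, 3, 2, 1, 0, -1, -2, -3, -4])
        p = empirical_p(v)
        assert p[0] == p[1] == pytest.approx(0.2)  # brute-force: 2 of 10 >= 5

    def test_nan_scores_excluded_from_distribution(self):
        v = np.array([np.nan, 2.0, 1.0])
        p = empirical_p(v)
        assert np.isnan(p[0]) and p[1] == pytest.approx(0.5)

    def test_empty_channel_errors(self):
        with pytest.raises(ValueError):
            empirical_p(np.array([]))

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=80))
    def test_monotone_non_increasing_in_value(self, vals):
        v = np.asarray(vals)
        p = empirical_p(v)
        order = np.argsort(v)
        assert np.all(np.diff(p[order]) <= 1e-15)

    def test_reference_ranking_matches_brute_force(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=500)
        vals = rng.normal(size=40)
        p = empirical_p_of(vals, ref)
        brute = [(ref >= x).mean() for x in vals]
        assert np.allclose(p, brute)


class TestClassify:
    def _table(self, values):
        return pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(1, len(values) + 1),
                "channel": "fst:AFR:EUR",
                "value": values,
            }
        )

    def test_exact_tail_counts_on_distinct_scores(self):
        rng = np.random.default_rng(2)
        out = classify(self._table(rng.permutation(1000).astype(float)))
        assert int(out["significant"].sum()) == 50
        assert int(out["candidate"].sum()) == 1
        assert (out["empirical_p"] > 0).all()

    def test_tier_flags_nested(self):
        rng = np.random.default_rng(3)
        out = classify(self._table(rng.normal(size=5000)))
        assert (out["stringent"] <= out["candidate"]).all()
        assert (out["candidate"] <= out["significant"]).all()

    def test_flag_counts_invariant_under_permutation(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=2000)
        a = classify(self._table(vals))
        b = classify(self._table(rng.permutation(vals)))
        for col in ("significant", "candidate", "stringent"):
            assert a[col].sum() == b[col].sum()

    def test_non_nested_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify(self._table(np.arange(1500.0)), alpha_candidate=0.2)

    def test_channels_ranked_separately(self):
        df = pd.concat(
            [
                self._table(np.arange(1000.0)),
                self._table(np.arange(1000.0) * 10).assign(channel="other"),
            ],
            ignore_index=True,
        )
        out = classify(df)
        by = out.groupby("channel")["significant"].sum()
        assert (by == 50).all()


class TestGeneSlice:
    def _scores(self):
        return pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(1, 300_001, 37),
                "channel": "c",
                "value": 1.0,
            }
        )

    def test_flank_boundary_is_closed(self):
        df = pd.DataFrame(
            {"chrom": "1", "pos": [89_999, 90_000, 160_000, 160_001],
             "channel": "c", "value": 1.0}
        )
        sl = gene_snp_slice(df, "1", 100_000, 150_000, flank=10_000)
        assert sorted(sl["pos"]) == [90_000, 160_000]

    def test_zero_flank_is_gene_body_only(self):
        df = self._scores()
        sl = gene_snp_slice(df, "1", 1_000, 2_000, flank=0)
        assert ((sl["pos"] >= 1_000) & (sl["pos"] <= 2_000)).all()

    def test_tiling_covers_every_snp_exactly_once(self):
        df = self._scores()
        tiles = [(s + 1, s + 50_000) for s in range(0, 300_000, 50_000)]
        got = pd.concat(
            [gene_snp_slice(df, "1", a, b, flank=0) for a, b in tiles]
        )
        assert len(got) == len(df)
        assert set(got["pos"]) == set(df["pos"])

    def test_absent_chromosome_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            sl = gene_snp_slice(self._scores(), "chr9", 10, 100)
        assert sl.empty
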