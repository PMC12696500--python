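"""Gene-set catalogs and density-matched background regions."""

import numpy as np
import pandas as pd
import pytest

from sweepset.genesets import (
    CatalogError,
    GeneRegion,
    build_background_sets,
    load_catalog,
    sample_background,
    snp_density,
)


def _catalog_df():
    rows = [
        ("g1", "1", 1000, 3000, "zinc", ""),
        ("g2", "1", 8000, 9000, "zinc", ""),
        ("g3", "2", 500, 2500, "iron", ""),
        ("g_shared", "2", 4000, 7000, "zinc,iron", "iron"),
    ]
    return pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "micronutrients",
                       "primary"]
    )


class TestCatalog:
    def test_fixture_catalog_has_thirteen_sets(self, fixture_dir):
        cat = load_catalog(fixture_dir["catalog"])
        assert len(cat.labels) == 13
        shared = [g for g in cat.genes.values() if len(g.micronutrients) > 1]
        assert shared, "fixture should include a multi-micronutrient gene"

    def test_overlapping_mode_lists_gene_in_both_sets(self):
        cat = load_catalog(_catalog_df())
        assert "g_shared" in cat.sets["zinc"] and "g_shared" in cat.sets["iron"]

    def test_non_overlapping_uses_primary(self):
        cat = load_catalog(_catalog_df(), mode="non_overlapping")
        assert "g_shared" in cat.sets["iron"]
        assert "g_shared" not in cat.sets["zinc"]

    def test_non_overlapping_without_primary_errors(self):
        df = _catalog_df()
        df.loc[df["gene"] == "g_shared", "primary"] = ""
        with pytest.raises(CatalogError):
            load_catalog(df, mode="non_overlapping")

    def test_duplicate_gene_names_error(self):
        df = pd.concat([_catalog_df()] * 2)
        with pytest.raises(CatalogError):
            load_catalog(df)

    def test_invalid_coordinates_error(self):
        with pytest.raises(CatalogError):
            GeneRegion("bad", "1", 100, 100, ("zinc",))


def _snp_positions(rng, chroms=("1", "2"), n=4000, span=200_000):
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, size=n),
            "pos": rng.integers(1, span, size=n),
        }
    )


def _universe(rng, chroms=("1", "2"), n=2500, span=200_000):
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, size=n),
            "start": rng.integers(0, span, size=n),
        }
    ).drop_duplicates()


class TestBackgroundSampling:
    def setup_method(self):
        self.rng = np.random.default_rng(10)
        self.gene = GeneRegion("g1", "1", 50_000, 60_000, ("zinc",))
        self.snps = _snp_positions(self.rng)
        self.universe = _universe(self.rng)
        self.lengths = {"1": 250_000, "2": 250_000}

    def test_default_keeps_1000_of_1500(self):
        kept = sample_background(
            self.gene, self.universe, self.snps, self.lengths,
            n_sample=1500, keep_n=1000, seed=1,
        )
        assert len(kept) == 1000

    def test_regions_match_gene_length_exactly(self):
        kept = sample_background(
            self.gene, self.universe, self.snps, self.lengths,
            n_sample=300, keep_n=200, seed=1,
        )
        assert ((kept["end"] - kept["start"]) == self.gene.length).all()

    def test_kept_set_matches_brute_force_sort(self):
        kept = sample_background(
            self.gene, self.universe, self.snps, self.lengths,
            n_sample=400, keep_n=150, seed=2,
        )
        # every kept delta must be <= every possible discarded delta, and the
        # kept set is the delta-sorted head with start-coordinate tie-break
        deltas = kept["delta"].to_numpy()
        assert (np.diff(np.sort(deltas)) >= 0).all()
        full = sample_background(
            self.gene, self.universe, self.snps, self.lengths,
            n_sample=400, keep_n=400, seed=2,
        )
        brute = full.sort_values(["delta", "start", "chrom"],
                                 kind="stable").head(150)
        assert set(zip(brute["chrom"], brute["start"])) == set(
            zip(kept["chrom"], kept["start"])
        )

    def test_mean_kept_delta_not_worse_than_any_discarded(self):
        full = sample_background(
            self.gene, self.universe, self.snps, self.lengths,
            n_sample=400, keep_n=400, seed=3,
        )
        kept = sample_background(
            self.gene, self.universe, self.snps, self.lengths,
            n_sample=400, keep_n=100, seed=3,
        )
        discarded = full[
            ~full.set_index(["chrom", "start"]).index.isin(
                kept.set_index(["chrom", "start"]).index
            )
        ]
        assert kept["delta"].mean() <= discarded["delta"].min() + 1e-12

    def test_deterministic_per_seed(self):
        a = sample_background(self.gene, self.universe, self.snps,
                              self.lengths, n_sample=200, keep_n=50, seed=5)
        b = sample_background(self.gene, self.universe, self.snps,
                              self.lengths, n_sample=200, keep_n=50, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_small_universe_errors(self):
        small = self.universe.head(999)
        with pytest.raises(CatalogError):
            sample_background(self.gene, small, self.snps, self.lengths,
                              n_sample=1500, keep_n=1000, seed=0)

    def test_candidates_never_overlap_focal_gene(self):
        kept = sample_background(
            self.gene, self.universe, self.snps, self.lengths,
            n_sample=300, keep_n=300, seed=6,
        )
        same = kept[kept["chrom"] == self.gene.chrom]
        no_overlap = (same["end"] <= self.gene.start - 10_000) | (
            same["start"] >= self.gene.end + 10_000
        )
        assert no_overlap.all()

    def test_density_definition(self):
        snps = pd.DataFrame({"chrom": ["1"] * 4, "pos": [5, 10, 100, 101]})
        # 0-based half-open [9, 100) covers 1-based positions 10..100
        assert snp_density(snps, "1", 9, 100) == pytest.approx(2 / 91)


class TestBackgroundSets:
    def test_sets_mirror_gene_counts_and_seeds(self):
        rng = np.random.default_rng(0)
        cat = load_catalog(_catalog_df())
        pools = {
            g: pd.DataFrame(
                {"chrom": "1", "start": rng.integers(0, 1000, 30)}
            ).assign(end=lambda d: d["start"] + 100)
            for g in cat.genes
        }
        sets = build_background_sets(cat, pools, n_sets=40, seed=1)
        assert sets.n_sets == 40
        for label in cat.labels:
            assert sets.indices[label].shape == (40, len(cat.sets[label]))
        other = build_background_sets(cat, pools, n_sets=40, seed=2)
        assert any(
            not np.array_equal(sets.indices[lbl], other.indices[lbl])
            for lbl in cat.labels
        )
        regions = sets.regions("zinc", 0)
        assert len(regions) == len(cat.sets["zinc"])

    def test_missing_pool_errors(self):
        cat = load_catalog(_catalog_df())
        with pytest.raises(CatalogError):
            build_background_sets(cat, {}, n_sets=5, seed=0)
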