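"""VCF/BED/score-table IO, filtering semantics and round trips."""

import numpy as np
import pandas as pd
import pytest

from sweepset.demography import build_demography
from sweepset.simulate import SimParams, run_neutral, sample_vcf
from sweepset.variant_io import (
    RegionMask,
    VariantIOError,
    read_bed,
    read_scores,
    read_vcf,
    write_results,
)

MISSING = -1


def test_fixture_filters_remove_each_class(fixture_dir):
    mask = read_bed(fixture_dir["mask"])
    table = read_vcf(
        fixture_dir["vcf"], sample_pops=fixture_dir["samples"], mask=mask
    )
    c = table.filter_counts
    assert c["indel"] >= 1
    assert c["multiallelic"] >= 1
    assert c["outside_mask"] >= 1
    assert c["high_missingness"] >= 1
    assert c["retained"] == table.n_variants
    # the kept toy record survived every filter
    toy = table.variants[table.variants["chrom"] == "toy1"]
    assert list(toy["pos"]) == [100]


def test_missingness_boundary_is_strictly_greater(tmp_path):
    # 1 missing call among 11 samples is 9.1% <= 10%: retained
    names = [f"P_{i}" for i in range(11)]
    gts = ["./."] + ["0|1"] * 10
    vcf = tmp_path / "m.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n##contig=<ID=c1,length=1000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(names)
        + "\nc1\t5\t.\tA\tG\t.\tPASS\t.\tGT\t"
        + "\t".join(gts)
        + "\n"
    )
    pops = pd.Series(["P"] * 11, index=names)
    table = read_vcf(str(vcf), sample_pops=pops, max_missing_frac=0.10)
    assert table.n_variants == 1
    assert table.dosage[0, 0] == MISSING


def test_half_call_treated_as_missing(tmp_path):
    names = ["a", "b"]
    vcf = tmp_path / "h.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n##contig=<ID=c1,length=100>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
        "c1\t5\t.\tA\tG\t.\tPASS\t.\tGT\t./1\t1|1\n"
    )
    table = read_vcf(
        str(vcf), sample_pops=pd.Series(["x", "x"], index=names),
        max_missing_frac=0.6,
    )
    assert table.dosage[0, 0] == MISSING
    assert table.dosage[0, 1] == 2


def test_bed_zero_based_half_open_covers_vcf_positions():
    mask = RegionMask.from_intervals([("chr1", 0, 100)])
    assert mask.contains("chr1", np.array([1]))[0]
    assert mask.contains("chr1", np.array([100]))[0]
    assert not mask.contains("chr1", np.array([101]))[0]


def test_empty_mask_retains_nothing(fixture_dir):
    empty = RegionMask.from_intervals([])
    table = read_vcf(
        fixture_dir["vcf"], sample_pops=fixture_dir["samples"], mask=empty
    )
    assert table.n_variants == 0


def test_mask_intervals_normalized_and_merged():
    mask = RegionMask.from_intervals(
        [("c", 50, 100), ("c", 0, 60), ("c", 200, 300)]
    )
    assert mask.intervals["c"].tolist() == [[0, 100], [200, 300]]
    assert mask.total_span == 200


def test_filter_composition_is_order_independent(fixture_dir):
    """Same retained set whether the mask is applied during or after reading."""
    mask = read_bed(fixture_dir["mask"])
    both = read_vcf(
        fixture_dir["vcf"], sample_pops=fixture_dir["samples"], mask=mask
    )
    unmasked = read_vcf(fixture_dir["vcf"], sample_pops=fixture_dir["samples"])
    keep = [
        i
        for i, (c, p) in enumerate(
            zip(unmasked.variants["chrom"], unmasked.variants["pos"])
        )
        if mask.contains(c, np.array([p]))[0]
    ]
    after = unmasked.variants.iloc[keep].reset_index(drop=True)
    pd.testing.assert_frame_equal(
        both.variants.reset_index(drop=True), after
    )


def test_simulated_region_round_trips_through_vcf(tmp_path):
    model = build_demography()
    region = run_neutral(
        model,
        SimParams(region_length=20_000, rescale_factor=64.0, sample_size=10,
                  seed=3),
    )
    vcf = tmp_path / "r.vcf"
    samples = tmp_path / "r.samples.tsv"
    sample_vcf(region, str(vcf), samples_path=str(samples))
    table = read_vcf(str(vcf), sample_pops=str(samples))
    assert table.n_variants == region.n_sites
    assert np.array_equal(table.variants["pos"].to_numpy(), region.positions)
    for pop in region.haplotypes:
        expect = region.dosage(pop)
        got = table.population_dosage(pop).T
        assert np.array_equal(got, expect)
    # fully phased input preserves haplotypes
    for pop in region.haplotypes:
        assert np.array_equal(
            table.population_haplotypes(pop).T, region.haplotypes[pop]
        )


def test_unknown_samples_in_population_map_error(fixture_dir):
    with pytest.raises(VariantIOError):
        read_vcf(fixture_dir["vcf"], sample_pops=pd.Series({"zzz": "AFR"}))


def test_score_table_schema_and_duplicates(tmp_path, fixture_dir):
    df = read_scores(fixture_dir["scores"])
    assert {"chrom", "pos", "population", "channel", "value",
            "channel_key"} <= set(df.columns)
    dup = pd.concat([df.drop(columns="channel_key")] * 2)
    path = tmp_path / "dup.tsv"
    dup.to_csv(path, sep="\t", index=False)
    with pytest.raises(VariantIOError):
        read_scores(str(path))


def test_write_results_is_deterministic(tmp_path):
    df = pd.DataFrame({"b": [1.0, 2.0], "a": ["x", "y"]})
    p1 = write_results({"t": df}, str(tmp_path / "o1"))[0]
    p2 = write_results({"t": df}, str(tmp_path / "o2"))[0]
    assert open(p1).read() == open(p2).read()
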