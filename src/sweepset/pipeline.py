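"""End-to-end orchestration: staged runs, fixtures, and run manifests.

A run is described by a structured YAML/dict config naming the stages to
execute among {simulate, filter, fst, scan, background, sumstat, enrich,
power}.  Stages run in dependency order, exchange artifacts through the
output directory (TSV/VCF/JSON only), and one manifest records the config
snapshot, the per-stage seeds fanned out deterministically from the global
seed, and per-stage record counts, so every result table is regenerable
from the manifest plus the inputs.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .demography import build_demography
from .empirical import classify, gene_snp_slice
from .enrichment import sumstat, sumstat_significance, tail_enrichment
from .fst import pairwise_scan
from .genesets import build_background_sets, load_catalog, sample_background
from .power import DEFAULT_POWER_PARAMS, PowerScenario, power_grid
from .simulate import SelectionEvent, SimParams, run_neutral, run_selected
from .variant_io import (
    RegionMask,
    read_bed,
    read_scores,
    read_vcf,
    write_region_vcf,
    write_results,
)

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "make_fixtures", "ConfigError", "STAGES"]

STAGES = (
    "simulate",
    "filter",
    "fst",
    "scan",
    "background",
    "sumstat",
    "enrich",
    "power",
)

MICRONUTRIENTS = (
    "calcium",
    "chloride",
    "copper",
    "iodine",
    "iron",
    "magnesium",
    "manganese",
    "molybdenum",
    "phosphorus",
    "potassium",
    "selenium",
    "sodium",
    "zinc",
)


class ConfigError(ValueError):
    pass


def _load_config(config) -> dict:
    if isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping or a YAML file path")
    return config


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).generate_state(len(STAGES))
    return {stage: int(s) % 2**31 for stage, s in zip(STAGES, children)}


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_fixtures(outdir: str, seed: int = 0, n_regions: int = 6) -> dict[str, str]:
    """Write a small synthetic dataset exercising every reader and filter.

    Simulates ``n_regions`` 20-kbp regions of the four-population model
    (heavily rescaled) as contigs sim1..simN of one VCF, then appends a toy
    contig with one indel, one triallelic record, one record outside the
    accessibility mask and one with >10% missing calls.  Also writes the
    sample-population map, a BED mask, a 13-set gene catalog (with one
    gene shared between two sets), a gene-universe table and an external
    score channel.  Deterministic per seed; different seeds move positions
    but keep the schema.
    """
    os.makedirs(outdir, exist_ok=True)
    model = build_demography()
    L = 20_000
    params_base = dict(
        region_length=L, rescale_factor=64.0, sample_size=10
    )
    seeds = np.random.SeedSequence([seed, 17]).generate_state(n_regions)
    vcf_lines: list[str] = []
    sample_names: list[str] = []
    regions = []
    for k in range(n_regions):
        p = SimParams(seed=int(seeds[k]) % 2**31, **params_base)
        region = run_neutral(model, p)
        regions.append(region)
        if not sample_names:
            for pop in region.haplotypes:
                n_dip = region.haplotypes[pop].shape[0] // 2
                sample_names.extend(f"{pop}_{i}" for i in range(n_dip))

    header = [
        "##fileformat=VCFv4.2",
        "##source=sweepset-fixtures",
    ]
    for k in range(n_regions):
        header.append(f"##contig=<ID=sim{k + 1},length={L}>")
    header.append(f"##contig=<ID=toy1,length={L}>")
    header.append(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    header.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_names)
    )
    body = []
    for k, region in enumerate(regions):
        hap = region.pooled()
        for j, pos in enumerate(region.positions):
            col = hap[:, j]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}"
                for i in range(len(sample_names))
            )
            body.append(
                f"sim{k + 1}\t{int(pos)}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}"
            )
    # toy contig: records exercising each filter branch
    n = len(sample_names)
    ref_gt = "\t".join(["0|0"] * n)
    some_alt = "\t".join(["0|1"] + ["0|0"] * (n - 1))
    n_missing = max(2, int(0.2 * n))
    missing_gt = "\t".join([".|."] * n_missing + ["0|1"] * (n - n_missing))
    body.append(f"toy1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t{some_alt}")  # kept
    body.append(f"toy1\t200\t.\tAT\tA\t.\tPASS\t.\tGT\t{some_alt}")  # indel
    body.append(f"toy1\t300\t.\tA\tG,C\t.\tPASS\t.\tGT\t{ref_gt}")  # triallelic
    body.append(f"toy1\t15000\t.\tA\tG\t.\tPASS\t.\tGT\t{some_alt}")  # masked out
    body.append(f"toy1\t400\t.\tA\tG\t.\tPASS\t.\tGT\t{missing_gt}")  # missing
    vcf_path = os.path.join(outdir, "fixture.vcf")
    with open(vcf_path, "w") as fh:
        fh.write("\n".join(header + body) + "\n")

    samples_path = os.path.join(outdir, "samples.tsv")
    with open(samples_path, "w") as fh:
        for name in sample_names:
            fh.write(f"{name}\t{name.rsplit('_', 1)[0]}\n")

    mask_path = os.path.join(outdir, "mask.bed")
    with open(mask_path, "w") as fh:
        for k in range(n_regions):
            fh.write(f"sim{k + 1}\t0\t{L}\n")
        fh.write("toy1\t0\t10000\n")  # excludes the record at 15,000

    # gene catalog: 13 sets tiling the simulated contigs; one shared gene
    rng = np.random.default_rng([seed, 23])
    rows = []
    gene_id = 0
    for label in MICRONUTRIENTS:
        for _ in range(2):
            chrom = f"sim{rng.integers(1, n_regions + 1)}"
            start = int(rng.integers(0, L - 4000))
            end = start + int(rng.integers(1000, 4000))
            rows.append((f"G{gene_id:03d}", chrom, start, end, label, ""))
            gene_id += 1
    # one gene associated with two micronutrients (primary: the first)
    rows.append(
        ("G_SHARED", "sim1", 2000, 6000, "zinc,selenium", "zinc")
    )
    catalog_path = os.path.join(outdir, "catalog.tsv")
    pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "micronutrients", "primary"]
    ).to_csv(catalog_path, sep="\t", index=False)

    universe_rows = [
        (f"sim{rng.integers(1, n_regions + 1)}", int(rng.integers(0, L - 5000)))
        for _ in range(4000)
    ]
    universe_path = os.path.join(outdir, "gene_universe.tsv")
    pd.DataFrame(universe_rows, columns=["chrom", "start"]).drop_duplicates().to_csv(
        universe_path, sep="\t", index=False
    )

    # external score channel on a handful of simulated SNPs
    sc_rows = []
    for k, region in enumerate(regions[:2]):
        for pos in region.positions[:: max(1, region.n_sites // 20)]:
            sc_rows.append(
                (
                    f"sim{k + 1}",
                    int(pos),
                    "EUR",
                    "ext_log10p",
                    float(np.round(rng.exponential(1.0), 4)),
                )
            )
    scores_path = os.path.join(outdir, "scores.tsv")
    pd.DataFrame(
        sc_rows, columns=["chrom", "pos", "population", "channel", "value"]
    ).to_csv(scores_path, sep="\t", index=False)

    return {
        "vcf": vcf_path,
        "samples": samples_path,
        "mask": mask_path,
        "catalog": catalog_path,
        "universe": universe_path,
        "scores": scores_path,
    }


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: dict | str, outdir: str | None = None) -> dict:
    """Execute the configured stages and write results plus one manifest.

    Returns the manifest dict.  The global ``seed`` fans out to per-stage
    seeds deterministically; identical config and seed give identical
    result tables.
    """
    cfg = _load_config(config)
    outdir = outdir or cfg.get("outdir", "sweepset_out")
    os.makedirs(outdir, exist_ok=True)
    stages = cfg.get("stages")
    if not stages:
        raise ConfigError("config must list at least one stage")
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stages {unknown}; valid: {list(STAGES)}")
    stages = [s for s in STAGES if s in stages]  # dependency order
    seed = int(cfg.get("seed", 0))
    seeds = _stage_seeds(seed)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": {s: seeds[s] for s in stages},
        "config": cfg,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    ctx: dict = {}

    for stage in stages:
        counts = _run_stage(stage, cfg.get(stage, {}) or {}, seeds[stage], outdir, ctx)
        manifest["stages"][stage] = counts
        log.info("stage %s: %s", stage, counts)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _require(ctx: dict, key: str, stage: str, option: str):
    if key not in ctx:
        raise ConfigError(
            f"stage {stage!r} needs {option!r} in its config or an upstream "
            "stage providing it"
        )
    return ctx[key]


def _run_stage(stage: str, scfg: dict, seed: int, outdir: str, ctx: dict) -> dict:
    if stage == "simulate":
        model = build_demography(scfg.get("demography"))
        n_sel = int(scfg.get("n_selected", 2))
        n_neu = int(scfg.get("n_neutral", 2))
        base = dict(
            region_length=int(scfg.get("region_length", 50_000)),
            rescale_factor=float(scfg.get("rescale_factor", 20.0)),
            sample_size=int(scfg.get("sample_size", 50)),
        )
        event = None
        if n_sel:
            sel = scfg.get("selection", {})
            s = sel.get("s", [0.001, 0.005])
            event = SelectionEvent(
                focal_population=sel.get("focal_population", "EUR"),
                onset_kya=float(sel.get("onset_kya", 40.0)),
                s=tuple(s) if isinstance(s, (list, tuple)) else float(s),
            )
        rep_seeds = np.random.SeedSequence([seed, 1]).generate_state(n_sel + n_neu)
        written = []
        for i in range(n_sel + n_neu):
            p = SimParams(seed=int(rep_seeds[i]) % 2**31, **base)
            if i < n_sel:
                region = run_selected(model, p, event)
                name = f"selected_{i}"
            else:
                region = run_neutral(model, p)
                name = f"neutral_{i - n_sel}"
            path = os.path.join(outdir, f"{name}.vcf")
            write_region_vcf(
                region,
                path,
                samples_path=os.path.join(outdir, "samples.tsv"),
                chrom=name,
            )
            written.append(path)
        ctx["vcf"] = written[-1]
        ctx["samples"] = os.path.join(outdir, "samples.tsv")
        ctx["simulated_vcfs"] = written
        return {"regions": len(written)}

    if stage == "filter":
        vcf = scfg.get("vcf") or _require(ctx, "vcf", stage, "vcf")
        samples = scfg.get("samples") or _require(ctx, "samples", stage, "samples")
        mask = None
        if scfg.get("mask"):
            mask = read_bed(scfg["mask"])
        table = read_vcf(
            vcf,
            sample_pops=samples,
            mask=mask,
            max_missing_frac=float(scfg.get("max_missing", 0.10)),
        )
        ctx["genotypes"] = table
        write_results(
            {"filter_counts": pd.DataFrame([table.filter_counts])}, outdir
        )
        return dict(table.filter_counts)

    if stage == "fst":
        table = _require(ctx, "genotypes", stage, "a filtered VCF (filter stage)")
        reference = scfg.get("reference", "AFR")
        scores = pairwise_scan(table, reference, scfg.get("tests"))
        ctx["scores"] = scores
        write_results({"fst_scores": scores}, outdir)
        return {
            "snps": int(scores["pos"].nunique()),
            "channels": int(scores["channel"].nunique()),
        }

    if stage == "scan":
        scores = ctx.get("scores")
        if scfg.get("scores"):
            scores = (
                read_scores(scfg["scores"])
                .drop(columns=["channel"])
                .rename(columns={"channel_key": "channel"})
            )[["chrom", "pos", "channel", "value"]]
        if scores is None:
            raise ConfigError("scan needs fst stage output or a scores file")
        flagged = classify(
            scores.dropna(subset=["value"]),
            alpha_candidate=float(scfg.get("alpha_candidate", 0.001)),
            alpha_significant=float(scfg.get("alpha_significant", 0.05)),
        )
        ctx["flagged"] = flagged
        write_results({"flagged_scores": flagged}, outdir)
        return {
            "scored": len(flagged),
            "significant": int(flagged["significant"].sum()),
            "candidate": int(flagged["candidate"].sum()),
        }

    if stage == "background":
        catalog = load_catalog(
            scfg.get("catalog") or _require(ctx, "catalog", stage, "catalog"),
            mode=scfg.get("mode", "overlapping"),
        )
        universe = pd.read_csv(
            scfg.get("universe") or _require(ctx, "universe", stage, "universe"),
            sep="\t",
            dtype={"chrom": str},
        )
        flagged = _require(ctx, "flagged", stage, "scan output")
        dens_pop = scfg.get("density_population", "AFR")
        chan = [c for c in flagged["channel"].unique() if dens_pop in c]
        snp_positions = flagged.loc[
            flagged["channel"] == (chan[0] if chan else flagged["channel"].iloc[0]),
            ["chrom", "pos"],
        ]
        chrom_lengths = scfg.get("chrom_lengths") or {
            c: int(flagged.loc[flagged["chrom"] == c, "pos"].max()) + 10_000
            for c in flagged["chrom"].unique()
        }
        rng = np.random.default_rng([seed, 3])
        pools = {}
        for gene in catalog.genes.values():
            pools[gene.name] = sample_background(
                gene,
                universe,
                snp_positions,
                chrom_lengths,
                n_sample=int(scfg.get("n_sample", 1500)),
                keep_n=int(scfg.get("keep", 1000)),
                seed=rng,
            )
        sets = build_background_sets(
            catalog, pools, n_sets=int(scfg.get("n_sets", 1000)), seed=rng
        )
        ctx["catalog_obj"] = catalog
        ctx["background_pools"] = pools
        ctx["background_sets"] = sets
        bed = pd.concat(pools.values(), ignore_index=True)
        write_results({"background_regions": bed}, outdir)
        return {"genes": len(pools), "sets_per_label": sets.n_sets}

    if stage == "sumstat":
        catalog = ctx.get("catalog_obj") or load_catalog(
            _require(ctx, "catalog", stage, "catalog")
        )
        sets = _require(ctx, "background_sets", stage, "background stage")
        flagged = _require(ctx, "flagged", stage, "scan output")
        flank = int(scfg.get("flank", 10_000))
        rows = []
        for channel, chan_df in flagged.groupby("channel"):
            for label in catalog.labels:
                gene_p = {}
                for gene in catalog.members(label):
                    sl = gene_snp_slice(
                        chan_df, gene.chrom, gene.start1, gene.end, flank
                    )
                    gene_p[gene.name] = sl["empirical_p"].to_numpy()
                try:
                    res = sumstat(gene_p, label=label, channel=channel)
                except ValueError:
                    continue
                nulls = []
                for k in range(sets.n_sets):
                    tot = 0.0
                    ok = True
                    for g, i in zip(
                        sets.genes_per_label[label], sets.indices[label][k]
                    ):
                        reg = sets.pools[g].iloc[int(i)]
                        sl = gene_snp_slice(
                            chan_df,
                            reg["chrom"],
                            int(reg["start"]) + 1,
                            int(reg["end"]),
                            flank,
                        )
                        vals = sl["empirical_p"].to_numpy()
                        if vals.size == 0:
                            ok = False
                            break
                        tot += float(np.nanmin(vals))
                    if ok:
                        nulls.append(tot)
                res = sumstat_significance(res, np.asarray(nulls), force=True)
                rows.append(
                    {
                        "label": label,
                        "channel": channel,
                        "sumstat": res.value,
                        "n_genes": res.n_genes_used,
                        "empirical_p": res.empirical_p,
                        **{f"tier_{t}": v for t, v in res.tiers.items()},
                    }
                )
        out = pd.DataFrame(rows)
        write_results({"sumstat": out}, outdir)
        ctx["sumstat"] = out
        return {"tests": len(out)}

    if stage == "enrich":
        catalog = ctx.get("catalog_obj") or load_catalog(
            _require(ctx, "catalog", stage, "catalog")
        )
        flagged = _require(ctx, "flagged", stage, "scan output")
        flank = int(scfg.get("flank", 10_000))
        rows = []
        for channel, chan_df in flagged.groupby("channel"):
            for label in catalog.labels:
                slices = [
                    gene_snp_slice(chan_df, g.chrom, g.start1, g.end, flank)
                    for g in catalog.members(label)
                ]
                sl = pd.concat(slices).drop_duplicates(subset=["chrom", "pos"])
                if not len(sl):
                    continue
                for alpha, flag in ((0.05, "significant"), (0.001, "candidate")):
                    res = tail_enrichment(
                        int(sl[flag].sum()), len(sl), alpha,
                        unit=label, channel=channel,
                    )
                    rows.append(asdict(res))
        out = pd.DataFrame(rows)
        write_results({"enrichment": out}, outdir)
        ctx["enrichment"] = out
        return {"tests": len(out)}

    if stage == "power":
        scenarios = [
            PowerScenario(
                focal_population=s.get("focal_population", "AFR"),
                onset_kya=float(s.get("onset_kya", 40.0)),
                n_selected=int(s.get("n_selected", 50)),
                n_neutral=int(s.get("n_neutral", 50)),
                set_size=s.get("set_size"),
                selected_fraction=s.get("selected_fraction"),
                seed=int(s.get("seed", seed)),
            )
            for s in scfg.get("grid", [{}])
        ]
        params = DEFAULT_POWER_PARAMS
        if "region_length" in scfg or "rescale_factor" in scfg:
            params = SimParams(
                region_length=int(scfg.get("region_length", 50_000)),
                rescale_factor=float(scfg.get("rescale_factor", 20.0)),
                sample_size=int(scfg.get("sample_size", 50)),
            )
        table = power_grid(
            scenarios,
            params=params,
            out_path=os.path.join(outdir, "power.tsv"),
        )
        ctx["power"] = table
        return {"cells": len(table)}

    raise ConfigError(f"unhandled stage {stage!r}")  # pragma: no cover
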