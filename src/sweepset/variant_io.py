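"""Readers, writers and filters for VCF / BED / score-table plumbing.

Coordinate conventions: VCF positions are 1-based; BED intervals are
0-based half-open, so the BED record ``chr1 0 100`` covers VCF positions
1..100 inclusive.  Genotype dosages are 0/1/2 with -1 as the missing
sentinel; half-calls (e.g. ``./1``) are treated as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeTable",
    "RegionMask",
    "read_vcf",
    "read_bed",
    "read_scores",
    "write_results",
    "write_region_vcf",
    "VariantIOError",
]

SCORE_COLUMNS = ["chrom", "pos", "population", "channel", "value"]


class VariantIOError(ValueError):
    pass


@dataclass
class RegionMask:
    """Accessibility mask: sorted, non-overlapping 0-based half-open intervals."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, records) -> "RegionMask":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in records:
            if start < 0 or end < start:
                raise VariantIOError(f"bad interval {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        out = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[chrom] = np.asarray(merged, dtype=np.int64).reshape(-1, 2)
        return cls(intervals=out)

    def contains(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Membership of 1-based position(s) in the mask."""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        ivs = self.intervals.get(str(chrom))
        if ivs is None or ivs.size == 0:
            return np.zeros(pos.shape, dtype=bool)
        zero_based = pos - 1
        idx = np.searchsorted(ivs[:, 0], zero_based, side="right") - 1
        ok = idx >= 0
        ok[ok] = zero_based[ok] < ivs[idx[ok], 1]
        return ok

    @property
    def total_span(self) -> int:
        return int(
            sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values())
        )


@dataclass
class GenotypeTable:
    """Filtered biallelic-SNP genotypes with a sample-to-population map.

    ``dosage`` is (n_variants, n_samples); ``haplotypes`` is
    (n_variants, 2 * n_samples) and only present when every genotype in the
    source was phased.
    """

    variants: pd.DataFrame
    dosage: np.ndarray
    samples: list[str]
    sample_pops: pd.Series
    haplotypes: np.ndarray | None = None
    filter_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.samples if s not in self.sample_pops.index]
        if unknown:
            raise VariantIOError(
                f"samples missing from the population map: {unknown[:5]}"
            )
        # positions strictly increasing per chromosome
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise VariantIOError(f"positions not strictly increasing on {chrom}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def populations(self) -> list[str]:
        seen = dict.fromkeys(self.sample_pops.loc[self.samples])
        return list(seen)

    def sample_indices(self, pop: str) -> np.ndarray:
        mask = self.sample_pops.loc[self.samples].to_numpy() == pop
        if not mask.any():
            raise KeyError(f"no samples for population {pop!r}")
        return np.nonzero(mask)[0]

    def population_dosage(self, pop: str) -> np.ndarray:
        return self.dosage[:, self.sample_indices(pop)]

    def population_haplotypes(self, pop: str) -> np.ndarray:
        if self.haplotypes is None:
            raise VariantIOError(
                "haplotype-level access requires fully phased genotypes"
            )
        idx = self.sample_indices(pop)
        cols = np.empty(2 * idx.size, dtype=np.int64)
        cols[0::2] = 2 * idx
        cols[1::2] = 2 * idx + 1
        return self.haplotypes[:, cols]


def read_bed(path: str) -> RegionMask:
    """Read a BED file (first three columns) as a :class:`RegionMask`."""
    records = []
    with open(path) as fh:
        for i, line in enumerate(line.rstrip("\n") for line in fh):
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise VariantIOError(f"{path}:{i + 1}: fewer than 3 BED columns")
            try:
                records.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise VariantIOError(f"{path}:{i + 1}: {exc}") from exc
    return RegionMask.from_intervals(records)


def read_sample_populations(path: str) -> pd.Series:
    """Two-column TSV sample -> population."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise VariantIOError(f"{path}: expected sample<TAB>population")
    return pd.Series(df[1].to_numpy(), index=df[0].astype(str)).astype(str)


def read_vcf(
    path: str,
    sample_pops: pd.Series | str,
    mask: RegionMask | None = None,
    max_missing_frac: float = 0.10,
) -> GenotypeTable:
    """Read a VCF, keeping masked biallelic SNPs with low missingness.

    Drops indels, multi-allelic records, sites outside ``mask`` (when
    given) and sites whose fraction of missing genotype calls exceeds
    ``max_missing_frac``.  The retained/removed counts per filter class
    are logged and recorded in ``filter_counts``.  The filters commute:
    the retained set does not depend on their order.
    """
    from cyvcf2 import VCF

    if isinstance(sample_pops, str):
        sample_pops = read_sample_populations(sample_pops)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VariantIOError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    counts = {
        "indel": 0,
        "multiallelic": 0,
        "outside_mask": 0,
        "high_missingness": 0,
        "retained": 0,
    }
    rows = []
    dosages = []
    haps = []
    all_phased = True
    for v in vcf:
        if len(v.ALT) != 1:
            counts["multiallelic"] += 1
            continue
        if not v.is_snp:
            counts["indel"] += 1
            continue
        if mask is not None and not mask.contains(v.CHROM, np.array([v.POS]))[0]:
            counts["outside_mask"] += 1
            continue
        gts = np.asarray(v.genotypes, dtype=np.int64)  # (n, 3): a, b, phased
        alleles = gts[:, :2]
        missing = (alleles < 0).any(axis=1)
        if missing.mean() > max_missing_frac:
            counts["high_missingness"] += 1
            continue
        dos = np.where(missing, -1, alleles.clip(min=0).sum(axis=1)).astype(np.int8)
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        dosages.append(dos)
        phased_here = bool(gts[~missing, 2].all()) if (~missing).any() else True
        all_phased = all_phased and phased_here and not missing.any()
        hap = alleles.astype(np.int8).reshape(-1)
        haps.append(hap)
        counts["retained"] += 1
    log.info("read_vcf %s: %s", path, counts)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosage = (
        np.vstack(dosages) if dosages else np.empty((0, len(samples)), dtype=np.int8)
    )
    haplotypes = None
    if all_phased and haps:
        haplotypes = np.vstack(haps)
    return GenotypeTable(
        variants=variants,
        dosage=dosage,
        samples=samples,
        sample_pops=sample_pops,
        haplotypes=haplotypes,
        filter_counts=counts,
    )


def read_scores(path: str) -> pd.DataFrame:
    """Read an external per-SNP score TSV.

    Schema: chrom, pos, population, channel, value.  Duplicate
    (chrom, pos, population, channel) rows are an error.  A combined
    ``channel_key`` column (``channel:population``) is added so external
    channels line up with internally computed ones.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "population": str})
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise VariantIOError(f"{path}: missing score columns {missing}")
    dup = df.duplicated(subset=["chrom", "pos", "population", "channel"])
    if dup.any():
        first = df[dup].iloc[0]
        raise VariantIOError(
            f"{path}: duplicate score row at {first['chrom']}:{first['pos']} "
            f"({first['channel']}, {first['population']})"
        )
    df = df.copy()
    df["channel_key"] = df["channel"].astype(str) + ":" + df["population"]
    return df


def write_results(tables: dict[str, pd.DataFrame], outdir: str) -> list[str]:
    """Write result tables as TSV with deterministic column order."""
    import os

    os.makedirs(outdir, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = os.path.join(outdir, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# VCF writing for simulated regions
# ---------------------------------------------------------------------------


def write_region_vcf(
    region,
    path: str,
    samples_path: str | None = None,
    chrom: str = "sim1",
) -> None:
    """Write a :class:`~sweepset.simulate.SimulatedRegion` as phased VCF 4.2.

    One column per diploid (named ``<POP>_<i>``), biallelic SNP records
    only, with the tagged selected site flagged ``SEL`` in INFO.  A sidecar
    sample-to-population TSV is written when ``samples_path`` is given.
    """
    pops = list(region.haplotypes)
    names = []
    for p in pops:
        n_dip = region.haplotypes[p].shape[0] // 2
        names.extend(f"{p}_{i}" for i in range(n_dip))
    L = int(region.metadata.get("region_length", max(region.positions, default=1)))
    lines = [
        "##fileformat=VCFv4.2",
        "##source=sweepset",
        f"##contig=<ID={chrom},length={L}>",
        '##INFO=<ID=SEL,Number=0,Type=Flag,Description="Tagged selected site">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names),
    ]
    hap_all = region.pooled()  # (2 * n_total, n_sites)
    for j, pos in enumerate(region.positions):
        col = hap_all[:, j]
        gts = "\t".join(
            f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(len(names))
        )
        info = "SEL" if region.selected_site == j else "."
        lines.append(f"{chrom}\t{int(pos)}\t.\tA\tG\t.\tPASS\t{info}\tGT\t{gts}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    if samples_path:
        with open(samples_path, "w") as fh:
            for p in pops:
                n_dip = region.haplotypes[p].shape[0] // 2
                for i in range(n_dip):
                    fh.write(f"{p}_{i}\t{p}\n")
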