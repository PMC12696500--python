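"""Micronutrient gene-set catalogs and matched background regions.

A catalog maps micronutrients to member gene regions (genes may belong to
several sets; a *non-overlapping* variant assigns each gene to its primary
micronutrient only).  For the set-level null, each gene gets a pool of
random background regions: starts drawn from the annotated gene universe,
length matched exactly to the gene, and the pool trimmed to the regions
with SNP density (in a designated reference population) closest to the
gene's own.  Background gene sets mirror the size of their micronutrient
set, one region drawn per member gene's pool.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GeneRegion",
    "GeneSetCatalog",
    "BackgroundSets",
    "load_catalog",
    "snp_density",
    "sample_background",
    "build_background_sets",
    "CatalogError",
]


class CatalogError(ValueError):
    pass


@dataclass(frozen=True)
class GeneRegion:
    """A gene region (0-based half-open coords) with micronutrient labels."""

    name: str
    chrom: str
    start: int
    end: int
    micronutrients: tuple[str, ...]
    primary: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise CatalogError(f"{self.name}: end must exceed start")
        if not self.micronutrients:
            raise CatalogError(f"{self.name}: at least one micronutrient label")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def start1(self) -> int:
        """1-based inclusive start (for SNP slicing)."""
        return self.start + 1


@dataclass
class GeneSetCatalog:
    """Micronutrient -> member genes, in overlapping or non-overlapping mode."""

    genes: dict[str, GeneRegion]
    sets: dict[str, list[str]]
    mode: str = "overlapping"

    @property
    def labels(self) -> list[str]:
        return list(self.sets)

    def members(self, label: str) -> list[GeneRegion]:
        return [self.genes[g] for g in self.sets[label]]


def load_catalog(source: str | pd.DataFrame, mode: str = "overlapping") -> GeneSetCatalog:
    """Load a gene catalog TSV (gene, chrom, start, end, micronutrients).

    ``micronutrients`` is a comma-separated label list; an optional
    ``primary`` column designates the single set a gene belongs to in
    ``non_overlapping`` mode (required there for multi-label genes).
    Duplicate gene names are an error; empty sets are retained with a
    warning.
    """
    if mode not in ("overlapping", "non_overlapping"):
        raise CatalogError(f"unknown catalog mode {mode!r}")
    if isinstance(source, str):
        df = pd.read_csv(source, sep="\t", dtype={"chrom": str})
    else:
        df = source.copy()
    required = ["gene", "chrom", "start", "end", "micronutrients"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CatalogError(f"catalog missing columns {missing}")
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise CatalogError(f"duplicate gene names: {dupes[:5]}")

    genes: dict[str, GeneRegion] = {}
    sets: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        labels = tuple(
            s.strip() for s in str(row.micronutrients).split(",") if s.strip()
        )
        primary = getattr(row, "primary", None)
        if isinstance(primary, float) and np.isnan(primary):
            primary = None
        gene = GeneRegion(
            name=str(row.gene),
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            micronutrients=labels,
            primary=str(primary) if primary else None,
        )
        genes[gene.name] = gene
        if mode == "non_overlapping" and len(labels) > 1:
            if gene.primary is None:
                raise CatalogError(
                    f"{gene.name}: multiple micronutrients {labels} but no "
                    "primary designation in non_overlapping mode"
                )
            if gene.primary not in labels:
                raise CatalogError(
                    f"{gene.name}: primary {gene.primary!r} not among labels"
                )
            membership = (gene.primary,)
        elif mode == "non_overlapping":
            membership = (gene.primary,) if gene.primary else labels
        else:
            membership = labels
        for label in membership:
            sets.setdefault(label, []).append(gene.name)
    for label, members in sets.items():
        if not members:
            warnings.warn(f"gene set {label!r} is empty", stacklevel=2)
    log.info(
        "loaded catalog: %d genes, %d sets (%s mode)", len(genes), len(sets), mode
    )
    return GeneSetCatalog(genes=genes, sets=sets, mode=mode)


def snp_density(
    snp_positions: pd.DataFrame, chrom: str, start: int, end: int
) -> float:
    """SNPs per bp inside a 0-based half-open region.

    ``snp_positions`` has columns (chrom, pos) with 1-based positions, from
    the designated density reference population.
    """
    sel = (
        (snp_positions["chrom"].astype(str) == str(chrom))
        & (snp_positions["pos"] > start)
        & (snp_positions["pos"] <= end)
    )
    return float(sel.sum()) / (end - start)


def sample_background(
    gene: GeneRegion,
    gene_universe: pd.DataFrame,
    snp_positions: pd.DataFrame,
    chrom_lengths: dict[str, int],
    n_sample: int = 1500,
    keep_n: int = 1000,
    seed: int | np.random.Generator = 0,
    exclusion_flank: int = 10_000,
) -> pd.DataFrame:
    """Length- and SNP-density-matched random regions for one gene.

    ``n_sample`` candidate regions start at distinct random annotated gene
    starts (columns chrom, start in ``gene_universe``) and share the focal
    gene's exact length; candidates running off the chromosome end or
    overlapping the focal gene (plus ``exclusion_flank``) are ineligible.
    The ``keep_n`` regions whose density is closest to the gene's own are
    retained (ties broken by lower start coordinate, then chromosome).
    Deterministic for a given seed.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if keep_n > n_sample:
        raise CatalogError("keep_n cannot exceed n_sample")
    length = gene.length
    uni = gene_universe[["chrom", "start"]].copy()
    uni["chrom"] = uni["chrom"].astype(str)
    uni = uni.drop_duplicates()
    end = uni["start"] + length
    fits = np.array(
        [
            e <= chrom_lengths.get(c, 0)
            for c, e in zip(uni["chrom"], end)
        ]
    )
    overlap = (
        (uni["chrom"] == gene.chrom)
        & (uni["start"] < gene.end + exclusion_flank)
        & (end > gene.start - exclusion_flank)
    ).to_numpy()
    eligible = uni.loc[fits & ~overlap].reset_index(drop=True)
    if len(eligible) < n_sample:
        raise CatalogError(
            f"{gene.name}: gene universe has only {len(eligible)} eligible "
            f"starts, need {n_sample}"
        )
    pick = rng.choice(len(eligible), size=n_sample, replace=False)
    cand = eligible.iloc[np.sort(pick)].reset_index(drop=True)
    cand["end"] = cand["start"] + length
    target = snp_density(snp_positions, gene.chrom, gene.start, gene.end)
    cand["density"] = [
        snp_density(snp_positions, c, s, e)
        for c, s, e in zip(cand["chrom"], cand["start"], cand["end"])
    ]
    cand["delta"] = (cand["density"] - target).abs()
    cand = cand.sort_values(
        ["delta", "start", "chrom"], kind="stable"
    ).reset_index(drop=True)
    kept = cand.iloc[:keep_n].reset_index(drop=True)
    kept.insert(0, "gene", gene.name)
    kept["target_density"] = target
    return kept


@dataclass
class BackgroundSets:
    """Background gene sets mirroring each micronutrient set's gene count.

    ``indices[label]`` has shape (n_sets, n_genes): row k holds, per member
    gene, the row index into that gene's background pool.
    """

    genes_per_label: dict[str, list[str]]
    indices: dict[str, np.ndarray]
    pools: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def n_sets(self) -> int:
        return next(iter(self.indices.values())).shape[0] if self.indices else 0

    def regions(self, label: str, k: int) -> pd.DataFrame:
        """The k-th background set for ``label`` as a region table."""
        rows = [
            self.pools[g].iloc[[i]]
            for g, i in zip(self.genes_per_label[label], self.indices[label][k])
        ]
        return pd.concat(rows, ignore_index=True)


def build_background_sets(
    catalog: GeneSetCatalog,
    pools: dict[str, pd.DataFrame],
    n_sets: int = 1000,
    seed: int | np.random.Generator = 0,
) -> BackgroundSets:
    """Assemble ``n_sets`` background sets per micronutrient.

    Each set matches its micronutrient set's gene count; every slot is one
    region drawn uniformly from the corresponding gene's matched pool.
    Deterministic per seed.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    missing = [
        g for members in catalog.sets.values() for g in members if g not in pools
    ]
    if missing:
        raise CatalogError(f"no background pool for genes: {sorted(set(missing))[:5]}")
    genes_per_label = {}
    indices = {}
    for label, members in catalog.sets.items():
        genes_per_label[label] = list(members)
        idx = np.empty((n_sets, len(members)), dtype=np.int64)
        for j, g in enumerate(members):
            idx[:, j] = rng.integers(0, len(pools[g]), size=n_sets)
        indices[label] = idx
    return BackgroundSets(
        genes_per_label=genes_per_label, indices=indices, pools=pools
    )
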