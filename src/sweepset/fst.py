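"""Per-SNP two-population Weir & Cockerham (1984) FST.

The estimator theta = a / (a + b + c) is computed from the three variance
components for r = 2 populations, using per-site sample sizes (missing
genotypes are excluded site by site), allele frequencies and observed
heterozygosities.  Raw theta is reported, including negative values; sites
where the denominator a + b + c is zero (e.g. monomorphic in both samples)
are *undefined* (NaN), which is distinct from theta = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FstRecord", "weir_cockerham_theta", "weir_cockerham_fst", "pairwise_scan"]


@dataclass(frozen=True)
class FstRecord:
    """theta at one site for one population pair (diploid counts used)."""

    chrom: str
    pos: int
    pop_a: str
    pop_b: str
    theta: float
    n_a: int
    n_b: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.theta)


def _site_summaries(dosage: np.ndarray):
    """Called-sample counts, alt-allele frequency and observed het per site.

    ``dosage`` is (n_diploids, n_sites) with 0/1/2 and -1 for missing.
    """
    dosage = np.asarray(dosage)
    called = dosage >= 0
    n = called.sum(axis=0)
    alt = np.where(called, dosage, 0).sum(axis=0)
    het = np.where(called, dosage == 1, False).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def weir_cockerham_theta(
    dosage_a: np.ndarray, dosage_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-site theta for two populations.

    Parameters are (n_diploids, n_sites) dosage matrices (0/1/2, -1 =
    missing).  Returns ``(theta, n_a, n_b)`` where undefined sites carry
    NaN: fewer than one called diploid in either population, n_bar <= 1,
    or a zero denominator.
    """
    dosage_a = np.atleast_2d(dosage_a)
    dosage_b = np.atleast_2d(dosage_b)
    n1, p1, h1 = _site_summaries(dosage_a)
    n2, p2, h2 = _site_summaries(dosage_b)

    r = 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        n_bar = (n1 + n2) / r
        n_tot = n1 + n2
        n_c = (n_tot - (n1**2 + n2**2) / n_tot) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / n_tot
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / n_tot

        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - s2 * (r - 1.0) / r
            - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0.0, a / denom, np.nan)

    bad = (n1 < 1) | (n2 < 1) | (n_bar <= 1.0) | ~np.isfinite(denom)
    theta = np.where(bad, np.nan, theta)
    return theta, n1, n2


def weir_cockerham_fst(
    dosage_a: np.ndarray,
    dosage_b: np.ndarray,
    chrom: str = ".",
    pos: int = 0,
    pop_a: str = "A",
    pop_b: str = "B",
) -> FstRecord:
    """Single-site convenience wrapper returning an :class:`FstRecord`."""
    dosage_a = np.asarray(dosage_a).reshape(-1, 1)
    dosage_b = np.asarray(dosage_b).reshape(-1, 1)
    theta, n1, n2 = weir_cockerham_theta(dosage_a, dosage_b)
    return FstRecord(
        chrom=chrom,
        pos=int(pos),
        pop_a=pop_a,
        pop_b=pop_b,
        theta=float(theta[0]),
        n_a=int(n1[0]),
        n_b=int(n2[0]),
    )


def pairwise_scan(
    table,
    reference_pop: str,
    test_pops: list[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP FST of every test population against a reference population.

    ``table`` is a :class:`~sweepset.variant_io.GenotypeTable`.  Returns a
    tidy score table with one channel ``fst:<ref>:<test>`` per pair
    (columns: chrom, pos, channel, value).  Undefined sites are emitted
    with NaN so that callers can exclude them from empirical distributions.
    """
    pops = table.populations
    if reference_pop not in pops:
        raise KeyError(f"unknown reference population {reference_pop!r}")
    if test_pops is None:
        test_pops = [p for p in pops if p != reference_pop]
    for p in test_pops:
        if p not in pops:
            raise KeyError(f"unknown test population {p!r}")
    ref = table.population_dosage(reference_pop)
    frames = []
    for p in test_pops:
        theta, _, _ = weir_cockerham_theta(ref.T, table.population_dosage(p).T)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": table.variants["chrom"].to_numpy(),
                    "pos": table.variants["pos"].to_numpy(),
                    "channel": f"fst:{reference_pop}:{p}",
                    "value": theta,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
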