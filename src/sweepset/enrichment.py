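"""Set-level selection tests: chi-squared tail enrichment and SUMSTAT.

Two complementary tests of positive selection acting on a gene set:

* ``tail_enrichment`` asks whether the set's SNPs hold more (or fewer)
  empirical-tail outliers than expected by chance: with T scored SNPs and a
  tail fraction alpha, the expected count is E = alpha * T, and the
  observed count O is compared with a 1-df chi-squared on the two cells
  (in tail, not in tail), without continuity correction.

* ``sumstat`` measures oligogenic/polygenic signal: the empirical p-value
  of the top-ranking SNP of each member gene (gene body plus flanks) is
  summed over the set; small sums mean several genes each carry a strong
  outlier.  Significance comes from the same sum computed over matched
  background gene sets (lower tail, pseudocount +1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "SumstatResult",
    "tail_enrichment",
    "sumstat_value",
    "sumstat",
    "sumstat_significance",
    "bonferroni_threshold",
]

SUMSTAT_TIERS = (0.05, 0.01, 0.001, 0.0001)


@dataclass(frozen=True)
class EnrichmentResult:
    """Chi-squared excess/deficit of tail SNPs in a gene-set slice."""

    unit: str
    alpha: float
    observed: int
    expected: float
    total: int
    chi2: float
    p: float
    direction: str
    percent_excess: float
    channel: str = ""


@dataclass
class SumstatResult:
    """SUMSTAT value for one (set, channel) with its background null."""

    label: str
    value: float
    per_gene_top_p: dict[str, float]
    n_genes_used: int
    n_genes_dropped: int
    channel: str = ""
    null_values: np.ndarray | None = None
    empirical_p: float | None = None
    tiers: dict[float, bool] = field(default_factory=dict)


def tail_enrichment(
    n_in_tail: int,
    n_total: int,
    alpha: float,
    unit: str = "",
    channel: str = "",
) -> EnrichmentResult:
    """Chi-squared test of tail-SNP excess or deficit.

    ``n_in_tail`` observed tail SNPs among ``n_total`` scored SNPs; the
    expectation under no enrichment is ``alpha * n_total``.  The statistic
    is (O-E)^2/E + ((T-O)-(T-E))^2/(T-E) with df = 1; the reported p is the
    chi-squared survival function (two-sided in the direction sense: the
    ``direction`` field says excess or deficit).
    """
    if n_total < 1:
        raise ValueError("no scored SNPs in the set (T = 0)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_in_tail > n_total:
        raise ValueError("observed tail count exceeds total")
    expected = alpha * n_total
    if expected < 5:
        warnings.warn(
            f"expected tail count {expected:.2f} < 5; chi-squared approximation "
            "is poor, consider the exact binomial cross-check",
            stacklevel=2,
        )
    o, e, t = float(n_in_tail), expected, float(n_total)
    chi2 = (o - e) ** 2 / e + ((t - o) - (t - e)) ** 2 / (t - e)
    p = float(stats.chi2.sf(chi2, df=1))
    direction = "excess" if o >= e else "deficit"
    return EnrichmentResult(
        unit=unit,
        alpha=alpha,
        observed=n_in_tail,
        expected=expected,
        total=n_total,
        chi2=float(chi2),
        p=p,
        direction=direction,
        percent_excess=100.0 * (o - e) / e,
        channel=channel,
    )


def binomial_cross_check(n_in_tail: int, n_total: int, alpha: float) -> float:
    """Exact two-sided binomial p for the same excess/deficit question."""
    return float(
        stats.binomtest(n_in_tail, n_total, alpha, alternative="two-sided").pvalue
    )


def sumstat_value(per_gene_top_p: dict[str, float]) -> float:
    """Sum of each member gene's minimum empirical p (its top SNP)."""
    return float(sum(per_gene_top_p.values()))


def sumstat(
    gene_pvalues: dict[str, np.ndarray],
    label: str = "",
    channel: str = "",
) -> SumstatResult:
    """SUMSTAT value for one gene set.

    ``gene_pvalues`` maps member genes to the empirical p-values of their
    scored SNPs (gene body plus flank).  Genes with no scored SNP are
    dropped with a warning and counted in the result.
    """
    per_gene: dict[str, float] = {}
    dropped = 0
    for gene, pvals in gene_pvalues.items():
        pvals = np.asarray(pvals, dtype=float)
        pvals = pvals[np.isfinite(pvals)]
        if pvals.size == 0:
            dropped += 1
            continue
        per_gene[gene] = float(pvals.min())
    if not per_gene:
        raise ValueError(f"gene set {label!r}: no member gene has scored SNPs")
    if dropped:
        warnings.warn(
            f"gene set {label!r}: {dropped} gene(s) without scored SNPs dropped",
            stacklevel=2,
        )
    return SumstatResult(
        label=label,
        value=sumstat_value(per_gene),
        per_gene_top_p=per_gene,
        n_genes_used=len(per_gene),
        n_genes_dropped=dropped,
        channel=channel,
    )


def sumstat_significance(
    result: SumstatResult | float,
    null_values: np.ndarray,
    force: bool = False,
) -> SumstatResult:
    """Empirical significance of a SUMSTAT value against background sums.

    Lower tail: smaller sums indicate stronger selection.  With the
    standard permutation pseudocount,
    ``p = (1 + #{null <= value}) / (n_null + 1)``, so a value below every
    null scores 1/(n+1), never zero.  Tier flags at 5%, 1%, 0.1% and 0.01%.
    """
    null_values = np.asarray(null_values, dtype=float)
    null_values = null_values[np.isfinite(null_values)]
    if null_values.size < 100 and not force:
        raise ValueError(
            f"only {null_values.size} background sums (< 100); pass force=True "
            "to accept a coarse null"
        )
    if isinstance(result, SumstatResult):
        value = result.value
    else:
        value = float(result)
        result = SumstatResult(
            label="", value=value, per_gene_top_p={}, n_genes_used=0,
            n_genes_dropped=0,
        )
    p = (1.0 + np.count_nonzero(null_values <= value)) / (null_values.size + 1.0)
    result.null_values = null_values
    result.empirical_p = float(p)
    result.tiers = {tier: p <= tier for tier in SUMSTAT_TIERS}
    return result


def bonferroni_threshold(n_tests: int) -> tuple[float, float]:
    """Family-wise 0.05 threshold for ``n_tests`` comparisons.

    Returns ``(threshold, threshold_3sf)``: the full-precision value
    0.05/n and its 3-significant-figure rounding as conventionally printed
    (e.g. 10,760 gene-population tests give 4.65e-6).
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    t = 0.05 / n_tests
    from math import floor, log10

    exp = floor(log10(abs(t)))
    rounded = round(t, -exp + 2)
    return t, rounded
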