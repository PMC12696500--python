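"""Empirical outlier classification of per-SNP selection scores.

Scores (FST or an external higher-is-stronger channel such as a
genealogy-based -log10 p) are ranked against the whole genome-wide score
distribution of their channel: the empirical p-value of a SNP is the
fraction of scores at least as large, ``p_i = #{j : v_j >= v_i} / N``
(closed tail, so the maximum scores p = 1/N and ties share a p-value).
SNPs in the 0.1% tail are *candidate* SNPs, SNPs in the 5% tail are
*significant* SNPs, and a stringent 0.01% tier is also flagged.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)

__all__ = ["empirical_p", "classify", "gene_snp_slice", "empirical_p_of"]

MIN_CHANNEL_SIZE = 1_000

TIERS = {
    "significant": 0.05,
    "candidate": 0.001,
    "stringent": 0.0001,
}


def empirical_p(values: np.ndarray) -> np.ndarray:
    """Per-value empirical tail probability against its own distribution.

    Non-finite entries do not enter the distribution and get NaN back.
    Monotone non-increasing in the value; ties share the same p.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty score channel")
    finite = np.isfinite(values)
    n = int(finite.sum())
    if n == 0:
        raise ValueError("score channel has no finite values")
    if n < MIN_CHANNEL_SIZE:
        warnings.warn(
            f"empirical distribution built from only {n} scores; "
            f"tail p-values are coarse below 1/{n}",
            stacklevel=2,
        )
    out = np.full(values.shape, np.nan)
    v = values[finite]
    # rank with ties taking the max rank counts #{v_j >= v_i}
    out[finite] = rankdata(-v, method="max") / n
    return out


def empirical_p_of(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Empirical p of ``values`` against a separate reference distribution.

    Used for the power analysis, where scores of simulated selected SNPs are
    ranked against the pooled scores of matched neutral simulations:
    ``p = #{ref >= v} / N_ref``.
    """
    ref = np.asarray(reference, dtype=float)
    ref = np.sort(ref[np.isfinite(ref)])
    if ref.size == 0:
        raise ValueError("empty reference distribution")
    values = np.asarray(values, dtype=float)
    ge = ref.size - np.searchsorted(ref, values, side="left")
    out = ge / ref.size
    return np.where(np.isfinite(values), out, np.nan)


def classify(
    scores: pd.DataFrame,
    alpha_candidate: float = 0.001,
    alpha_significant: float = 0.05,
    alpha_stringent: float = 0.0001,
    channel_col: str = "channel",
    value_col: str = "value",
) -> pd.DataFrame:
    """Attach empirical p-values and nested tier flags per channel.

    Input is a tidy score table (chrom, pos, channel, value).  Thresholds
    must be nested ``alpha_stringent < alpha_candidate < alpha_significant``
    and inside (0, 1); flags use the closed tail ``p <= alpha``, so with N
    distinct scores exactly ``floor(alpha * N)`` are flagged.
    """
    if not (0.0 < alpha_stringent < alpha_candidate < alpha_significant < 1.0):
        raise ValueError("alpha tiers must be nested inside (0, 1)")
    out = scores.copy()
    out["empirical_p"] = np.nan
    for _, idx in out.groupby(channel_col, sort=False).groups.items():
        out.loc[idx, "empirical_p"] = empirical_p(
            out.loc[idx, value_col].to_numpy()
        )
    out["significant"] = out["empirical_p"] <= alpha_significant
    out["candidate"] = out["empirical_p"] <= alpha_candidate
    out["stringent"] = out["empirical_p"] <= alpha_stringent
    n_chan = out[channel_col].nunique()
    log.info(
        "classified %d SNP scores in %d channel(s): %d significant, "
        "%d candidate, %d stringent",
        len(out),
        n_chan,
        int(out["significant"].sum()),
        int(out["candidate"].sum()),
        int(out["stringent"].sum()),
    )
    return out


def gene_snp_slice(
    scores: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    flank: int = 10_000,
) -> pd.DataFrame:
    """SNP rows within a gene body (1-based inclusive coords) plus flanks.

    Selects positions in ``[start - flank, end + flank]``, clipped at 1.
    An empty slice (e.g. gene on a chromosome absent from the table) is
    returned with a warning rather than an error.
    """
    if end < start:
        raise ValueError(f"gene end {end} before start {start}")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    lo = max(1, start - flank)
    hi = end + flank
    sel = (
        (scores["chrom"].astype(str) == str(chrom))
        & (scores["pos"] >= lo)
        & (scores["pos"] <= hi)
    )
    if not sel.any():
        warnings.warn(
            f"no scored SNPs in {chrom}:{lo}-{hi}; empty gene slice",
            stacklevel=2,
        )
    return scores.loc[sel]
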