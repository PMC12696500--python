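"""Power analysis of the FST outlier scan and the SUMSTAT set test.

True-positive rates are measured against the tails of a *neutral*
distribution built from matched neutral simulations (not within-dataset
empirical tails): a selected SNP counts as detected when its score reaches
the 95th percentile of the pooled per-SNP scores of the neutral replicates
for the same population pair.  At the set level, sets of simulated regions
are scored with SUMSTAT (sum over regions of the empirical p of each
region's top SNP, ranked against the pooled neutral scores) and called
against the lower 5% tail of sums over neutral background sets.

Scenario grid defaults follow the study design: selection onsets 1, 5, 10
and 40 kya in one of four focal populations, s ~ U[0.001, 0.005] on a
standing variant at initial frequency 0.10-0.15, gene sets of size 10-60
with 20-100% of members under selection.  The reduced default scale
(rescaling Q = 20, 50-kbp regions, 150 replicates per cell) is recorded in
every result so scaled runs are never conflated with full-scale ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .demography import DemographicModel, build_demography
from .empirical import empirical_p_of
from .fst import weir_cockerham_theta
from .simulate import (
    SelectionEvent,
    SimParams,
    run_neutral,
    run_selected,
)

log = logging.getLogger(__name__)

__all__ = [
    "PowerScenario",
    "PowerResult",
    "RegionScorePool",
    "reference_pair",
    "build_pool",
    "snp_power",
    "set_power",
    "power_grid",
    "DEFAULT_POWER_PARAMS",
]

ONSETS_KYA = (1.0, 5.0, 10.0, 40.0)
SET_SIZES = (10, 20, 40, 60)
SELECTED_FRACTIONS = (0.2, 0.4, 0.6, 0.8, 1.0)

#: reduced desk scale: Q=20 rescaling, 50-kbp regions, 50 diploids sampled
DEFAULT_POWER_PARAMS = SimParams(
    region_length=50_000,
    rescale_factor=20.0,
    sample_size=50,
)


@dataclass(frozen=True)
class PowerScenario:
    """One cell of the power grid."""

    focal_population: str
    onset_kya: float = 40.0
    s: float | tuple[float, float] = (0.001, 0.005)
    n_selected: int = 150
    n_neutral: int = 150
    set_size: int | None = None
    selected_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_selected < 1 or self.n_neutral < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.selected_fraction is not None and not (
            0.0 < self.selected_fraction <= 1.0
        ):
            raise ValueError("selected_fraction must be in (0, 1]")


@dataclass
class PowerResult:
    """TPR/FNR/FPR (percent) with binomial confidence intervals."""

    level: str
    tpr: float
    fnr: float
    fpr: float
    ci_low: float
    ci_high: float
    threshold: float
    n_used: int
    n_excluded: int
    scenario: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = dict(self.scenario)
        row.update(
            level=self.level,
            tpr=self.tpr,
            fnr=self.fnr,
            fpr=self.fpr,
            ci_low=self.ci_low,
            ci_high=self.ci_high,
            threshold=self.threshold,
            n_used=self.n_used,
            n_excluded=self.n_excluded,
        )
        return row


@dataclass
class RegionScorePool:
    """Per-replicate FST score summaries for one (population, onset) cell.

    ``selected_tagged`` holds the tagged SNP's score per selected replicate;
    ``selected_max``/``neutral_max`` hold each region's top score (the SNP
    feeding SUMSTAT); ``neutral_scores`` holds every neutral region's full
    per-SNP score vector, whose pool is the neutral null distribution.
    """

    focal: str
    reference: str
    selected_tagged: np.ndarray
    selected_max: np.ndarray
    selected_s: np.ndarray
    selected_final_freq: np.ndarray
    neutral_scores: list[np.ndarray]
    neutral_max: np.ndarray
    n_excluded: int
    meta: dict = field(default_factory=dict)

    @property
    def neutral_pooled(self) -> np.ndarray:
        return np.concatenate(self.neutral_scores)


def reference_pair(focal: str) -> tuple[str, str]:
    """Population pair for the per-SNP FST channel of a focal population.

    Every non-African population is paired with the African reference (the
    Yoruba role); the African focal population needs a non-focal out-pair
    and is paired with the European population.
    """
    return ("AFR", "EUR") if focal == "AFR" else (focal, "AFR")


def _wilson_ci(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
    if n == 0:
        return (0.0, 100.0)
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (100 * max(0.0, center - half), 100 * min(1.0, center + half))


def _region_theta(region, pop_a: str, pop_b: str) -> np.ndarray:
    theta, _, _ = weir_cockerham_theta(region.dosage(pop_a), region.dosage(pop_b))
    return theta


def build_pool(
    scenario: PowerScenario,
    model: DemographicModel | None = None,
    params: SimParams = DEFAULT_POWER_PARAMS,
) -> RegionScorePool:
    """Simulate the selected and matched neutral replicates of one cell.

    Selected replicates whose tagged allele is absent from the sample (or
    whose tagged-site FST is undefined for the scored pair) are excluded
    and counted.  Seeds fan out deterministically from ``scenario.seed``.
    """
    model = model or build_demography()
    focal, ref = reference_pair(scenario.focal_population)
    event = SelectionEvent(
        focal_population=scenario.focal_population,
        onset_kya=scenario.onset_kya,
        s=scenario.s,
    )
    seeds = np.random.SeedSequence(scenario.seed).generate_state(
        scenario.n_selected + scenario.n_neutral
    )
    tagged, smax, svals, ffreq = [], [], [], []
    excluded = 0
    for i in range(scenario.n_selected):
        p = SimParams(
            region_length=params.region_length,
            mutation_rate=params.mutation_rate,
            recombination_rate=params.recombination_rate,
            rescale_factor=params.rescale_factor,
            sample_size=params.sample_size,
            seed=int(seeds[i]) % 2**31,
        )
        region = run_selected(model, p, event)
        theta = _region_theta(region, focal, ref)
        finite = np.isfinite(theta)
        if (
            region.selected_site is None
            or not finite[region.selected_site]
            or not finite.any()
        ):
            excluded += 1
            continue
        tagged.append(theta[region.selected_site])
        smax.append(np.nanmax(theta))
        svals.append(region.metadata["s"])
        ffreq.append(float(region.trajectory[-1]))
    neutral_scores, nmax = [], []
    for i in range(scenario.n_neutral):
        p = SimParams(
            region_length=params.region_length,
            mutation_rate=params.mutation_rate,
            recombination_rate=params.recombination_rate,
            rescale_factor=params.rescale_factor,
            sample_size=params.sample_size,
            seed=int(seeds[scenario.n_selected + i]) % 2**31,
        )
        region = run_neutral(model, p)
        theta = _region_theta(region, focal, ref)
        theta = theta[np.isfinite(theta)]
        if theta.size == 0:
            continue
        neutral_scores.append(theta)
        nmax.append(theta.max())
    if not neutral_scores:
        raise RuntimeError("no defined neutral FST scores in this cell")
    log.info(
        "pool %s onset %.0f kya: %d selected used (%d excluded), %d neutral",
        scenario.focal_population,
        scenario.onset_kya,
        len(tagged),
        excluded,
        len(neutral_scores),
    )
    return RegionScorePool(
        focal=focal,
        reference=ref,
        selected_tagged=np.asarray(tagged),
        selected_max=np.asarray(smax),
        selected_s=np.asarray(svals),
        selected_final_freq=np.asarray(ffreq),
        neutral_scores=neutral_scores,
        neutral_max=np.asarray(nmax),
        n_excluded=excluded,
        meta={
            "scenario": asdict(scenario),
            "rescale_factor": params.rescale_factor,
            "region_length": params.region_length,
            "sample_size": params.sample_size,
        },
    )


def snp_power(
    scenario: PowerScenario,
    pool: RegionScorePool | None = None,
    model: DemographicModel | None = None,
    params: SimParams = DEFAULT_POWER_PARAMS,
    tail: float = 0.05,
) -> PowerResult:
    """SNP-level TPR of the FST scan against the neutral 95th percentile.

    The detection threshold is the (1 - tail) percentile of the pooled
    neutral per-SNP scores; TPR is the percentage of tagged selected SNPs
    at or above it.  FPR is estimated on held-out neutral replicates
    (threshold from one half, scored on the other).
    """
    pool = pool or build_pool(scenario, model=model, params=params)
    neutral_all = pool.neutral_pooled
    if neutral_all.size < 500:
        log.warning(
            "only %d pooled neutral scores; the 95th percentile is noisy",
            neutral_all.size,
        )
    threshold = float(np.percentile(neutral_all, 100 * (1 - tail)))
    n = pool.selected_tagged.size
    k = int(np.count_nonzero(pool.selected_tagged >= threshold))
    tpr = 100.0 * k / n if n else float("nan")
    ci = _wilson_ci(k, n)
    half = len(pool.neutral_scores) // 2
    thr_a = np.percentile(np.concatenate(pool.neutral_scores[:half]), 100 * (1 - tail))
    held = np.concatenate(pool.neutral_scores[half:])
    fpr = 100.0 * float(np.count_nonzero(held >= thr_a)) / held.size
    return PowerResult(
        level="snp",
        tpr=tpr,
        fnr=100.0 - tpr,
        fpr=fpr,
        ci_low=ci[0],
        ci_high=ci[1],
        threshold=threshold,
        n_used=n,
        n_excluded=pool.n_excluded,
        scenario=asdict(scenario),
    )


def set_power(
    scenario: PowerScenario,
    pool: RegionScorePool | None = None,
    model: DemographicModel | None = None,
    params: SimParams = DEFAULT_POWER_PARAMS,
    n_test_sets: int = 50,
    n_null_sets: int = 1000,
    tail: float = 0.05,
) -> PowerResult:
    """Set-level TPR of SUMSTAT-on-FST for one (size, fraction) cell.

    Test sets mix ``round(size * fraction)`` selected regions with neutral
    regions; each region contributes the empirical p of its top SNP against
    the pooled neutral distribution.  The null is ``n_null_sets`` sets of
    the same size drawn from the neutral region pool; a test set counts as
    detected when its sum falls in the null's lower ``tail`` with the +1
    pseudocount.
    """
    if scenario.set_size is None or scenario.selected_fraction is None:
        raise ValueError("set-level scenario needs set_size and selected_fraction")
    pool = pool or build_pool(scenario, model=model, params=params)
    rng = np.random.default_rng([scenario.seed, 0x5353])
    neutral_all = np.sort(pool.neutral_pooled)
    sel_minp = empirical_p_of(pool.selected_max, neutral_all)
    neut_minp = empirical_p_of(pool.neutral_max, neutral_all)
    size = scenario.set_size
    k_sel = int(round(size * scenario.selected_fraction))
    k_neu = size - k_sel
    if k_sel > sel_minp.size or k_neu > neut_minp.size:
        raise RuntimeError(
            f"region pools too small for sets of {size} "
            f"({sel_minp.size} selected, {neut_minp.size} neutral available)"
        )
    null_sums = np.array(
        [
            neut_minp[rng.choice(neut_minp.size, size=size, replace=False)].sum()
            for _ in range(n_null_sets)
        ]
    )
    detected = 0
    for _ in range(n_test_sets):
        total = (
            sel_minp[rng.choice(sel_minp.size, size=k_sel, replace=False)].sum()
            + neut_minp[rng.choice(neut_minp.size, size=k_neu, replace=False)].sum()
        )
        p = (1.0 + np.count_nonzero(null_sums <= total)) / (null_sums.size + 1.0)
        detected += p <= tail
    tpr = 100.0 * detected / n_test_sets
    ci = _wilson_ci(detected, n_test_sets)
    return PowerResult(
        level="set",
        tpr=tpr,
        fnr=100.0 - tpr,
        fpr=float("nan"),
        ci_low=ci[0],
        ci_high=ci[1],
        threshold=float(np.quantile(null_sums, tail)),
        n_used=n_test_sets,
        n_excluded=pool.n_excluded,
        scenario=asdict(scenario),
    )


def standard_power_pools(
    seed: int,
    n_selected: int = 150,
    n_neutral: int = 150,
    onset_kya: float = 40.0,
    populations: tuple[str, ...] = ("AFR", "EUR", "EAS", "AMR"),
    model: DemographicModel | None = None,
    params: SimParams = DEFAULT_POWER_PARAMS,
) -> dict[str, RegionScorePool]:
    """Region score pools for the headline power experiment.

    One pool per focal population at the given selection onset, each with
    ``n_selected`` retained selected replicates (s ~ U[0.001, 0.005] on a
    standing variant at frequency 0.10-0.15) and matched neutral
    replicates, at the reduced desk scale of ``params``.  Pool seeds fan
    out deterministically from ``seed``.
    """
    model = model or build_demography()
    kids = np.random.SeedSequence([seed, 0x40]).generate_state(len(populations))
    pools = {}
    for pop, child in zip(populations, kids):
        sc = PowerScenario(
            focal_population=pop,
            onset_kya=onset_kya,
            n_selected=n_selected,
            n_neutral=n_neutral,
            seed=int(child) % 2**31,
        )
        pools[pop] = build_pool(sc, model=model, params=params)
    return pools


def power_grid(
    scenarios: list[PowerScenario],
    model: DemographicModel | None = None,
    params: SimParams = DEFAULT_POWER_PARAMS,
    out_path: str | None = None,
) -> pd.DataFrame:
    """Run a list of scenarios into one tidy table (one row per cell).

    With ``out_path``, rows already present in the file (matched on the
    scenario columns) are kept and their cells skipped, making long grids
    resumable.  Cells that fail are flagged in an ``error`` column instead
    of being dropped.
    """
    model = model or build_demography()
    done = None
    key_cols = ["focal_population", "onset_kya", "set_size", "selected_fraction",
                "seed"]
    if out_path:
        import os

        if os.path.exists(out_path):
            done = pd.read_csv(out_path, sep="\t")
    rows = []
    for sc in scenarios:
        if done is not None and len(done):
            match = np.ones(len(done), dtype=bool)
            for col in key_cols:
                want = getattr(sc, col)
                have = done[col]
                match &= (
                    have.isna() if want is None else (have == want)
                ).to_numpy()
            if match.any():
                rows.extend(done.loc[match].to_dict("records"))
                continue
        try:
            pool = build_pool(sc, model=model, params=params)
            if sc.set_size is None:
                res = snp_power(sc, pool=pool)
            else:
                res = set_power(sc, pool=pool)
            row = res.to_row()
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - cell-level fault isolation
            log.error("cell %s failed: %s", sc, exc)
            row = asdict(sc)
            row.update(level="", tpr=np.nan, fnr=np.nan, fpr=np.nan, error=str(exc))
        rows.append(row)
        if out_path:
            pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False)
    return pd.DataFrame(rows)
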