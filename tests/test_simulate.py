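"""Forward-simulator behaviour: drift, selection, rescaling, determinism."""

import numpy as np
import pytest

import sweepset.simulate as sim
from sweepset.demography import build_demography, single_population_model
from sweepset.simulate import (
    SelectionEvent,
    SimParams,
    _Discard,
    _simulate_once,
    founder_from_freqs,
    run_neutral,
    run_selected,
)

from conftest import selection_recursion

SMALL = dict(region_length=20_000, rescale_factor=64.0, sample_size=10)


def test_no_mutation_single_founder_gives_zero_sites():
    m = single_population_model(40, 50)
    p = SimParams(region_length=1000, mutation_rate=0.0, sample_size=40, seed=0)
    region = run_neutral(m, p)
    assert region.n_sites == 0


def test_same_seed_gives_identical_output(tmp_path):
    m = build_demography()
    p = SimParams(seed=123, **SMALL)
    r1 = run_neutral(m, p)
    r2 = run_neutral(m, p)
    assert np.array_equal(r1.positions, r2.positions)
    for pop in r1.haplotypes:
        assert np.array_equal(r1.haplotypes[pop], r2.haplotypes[pop])
    a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
    sim.sample_vcf(r1, str(a))
    sim.sample_vcf(r2, str(b))
    assert a.read_bytes() == b.read_bytes()


def test_different_seeds_differ():
    m = build_demography()
    r1 = run_neutral(m, SimParams(seed=1, **SMALL))
    r2 = run_neutral(m, SimParams(seed=2, **SMALL))
    assert not np.array_equal(r1.positions, r2.positions)


def test_region_columns_segregate_in_pooled_sample():
    m = build_demography()
    region = run_neutral(m, SimParams(seed=5, **SMALL))
    pooled = region.pooled()
    counts = pooled.sum(axis=0)
    assert np.all(counts > 0) and np.all(counts < pooled.shape[0])
    assert np.all(np.diff(region.positions) > 0)


def test_numpy_fallback_matches_drift_expectation(monkeypatch):
    """The pure-numpy engine path shows the same (1 - 1/2N)^t decay."""
    monkeypatch.setattr(sim, "HAVE_NUMBA", False)
    N, T, reps = 60, 60, 300
    m = single_population_model(N, T)
    H0, pos = founder_from_freqs(N, [(500, 0.5)], np.random.default_rng(1))
    hets = []
    for i in range(reps):
        p = SimParams(
            region_length=1000, mutation_rate=0.0, recombination_rate=0.0,
            sample_size=N, seed=i,
        )
        r = run_neutral(m, p, founder=(H0, pos), track_position=500)
        f = r.metadata["tracked_trajectory"][-1]
        hets.append(2 * f * (1 - f))
    expected = 0.5 * (1 - 1 / (2 * N)) ** T
    assert np.mean(hets) == pytest.approx(expected, abs=0.03)


def test_large_population_selection_follows_deterministic_recursion():
    """Mean trajectory endpoint matches the one-locus recursion at large N."""
    N, T, s = 20_000, 200, 0.04
    m = single_population_model(N, T)
    ev = SelectionEvent("POP", (T - 1) * 28 / 1000, s=s, h=0.5,
                        f0_window=(0.09, 0.11))
    H0, pos = founder_from_freqs(N, [(500, 0.10)], np.random.default_rng(3))
    finals, oracle = [], []
    i = 0
    while len(finals) < 5 and i < 30:
        p = SimParams(region_length=1000, mutation_rate=0.0,
                      recombination_rate=0.0, sample_size=50, seed=i)
        rng = np.random.default_rng([i, 1])
        i += 1
        try:
            r = _simulate_once(m, p, rng, event=ev, founder=(H0, pos))
        except _Discard:
            continue
        finals.append(r.trajectory[-1])
        oracle.append(
            selection_recursion(r.trajectory[0], s, 0.5, len(r.trajectory) - 1)
        )
    assert np.mean(finals) == pytest.approx(np.mean(oracle), abs=0.04)


def test_selection_with_s_zero_behaves_neutrally():
    """s=0 trajectories show no systematic frequency change."""
    N, T = 1000, 150
    m = single_population_model(N, T)
    ev = SelectionEvent("POP", (T - 1) * 28 / 1000, s=0.0,
                        f0_window=(0.3, 0.5))
    H0, pos = founder_from_freqs(N, [(500, 0.40)], np.random.default_rng(5))
    deltas = []
    i = 0
    while len(deltas) < 40 and i < 200:
        p = SimParams(region_length=1000, mutation_rate=0.0,
                      recombination_rate=0.0, sample_size=50, seed=i)
        rng = np.random.default_rng([i, 2])
        i += 1
        try:
            r = _simulate_once(m, p, rng, event=ev, founder=(H0, pos))
        except _Discard:
            continue
        deltas.append(r.trajectory[-1] - r.trajectory[0])
    # drift is mean-zero: |mean delta| within 4 SE
    se = np.std(deltas) / np.sqrt(len(deltas))
    assert abs(np.mean(deltas)) < 4 * max(se, 1e-3)


def test_rescaled_run_reproduces_unscaled_diversity():
    """Q=1 and Q=10 give the same segregating-site and diversity levels."""
    N, T, L = 100, 1000, 10_000
    mu = 2.5e-7
    reps = 120
    stats = {}
    for q in (1.0, 10.0):
        m = single_population_model(N, T)
        n_s, pis = [], []
        for i in range(reps):
            p = SimParams(region_length=L, mutation_rate=mu,
                          recombination_rate=1.25e-8, rescale_factor=q,
                          sample_size=10, seed=i)
            r = run_neutral(m, p)
            H = r.pooled()
            f = H.mean(axis=0)
            n_s.append(r.n_sites)
            pis.append(np.sum(2 * f * (1 - f)))
        stats[q] = (np.mean(n_s), np.std(n_s), np.mean(pis), np.std(pis))
    for k in (0, 2):  # segregating sites, pairwise diversity
        diff = abs(stats[10.0][k] - stats[1.0][k])
        se = np.hypot(stats[10.0][k + 1], stats[1.0][k + 1]) / np.sqrt(reps)
        assert diff < 3.5 * se


def test_selected_run_tags_allele_in_window_and_records_trajectory():
    m = build_demography()
    p = SimParams(seed=9, **SMALL)
    ev = SelectionEvent("EUR", 40.0, s=(0.001, 0.005))
    region = run_selected(m, p, ev)
    traj = region.trajectory
    assert traj is not None and len(traj) > 1
    assert 0.10 <= traj[0] <= 0.15
    assert np.all((traj >= 0) & (traj <= 1))
    assert traj[-1] > 0  # retention: not lost
    assert 0.001 <= region.metadata["s"] <= 0.005


def test_selected_runs_sampled_vcf_flags_selected_site(tmp_path):
    m = build_demography()
    region = run_selected(
        m, SimParams(seed=11, **SMALL), SelectionEvent("AFR", 40.0)
    )
    if region.selected_site is None:
        pytest.skip("tagged allele monomorphic in this sample draw")
    out = tmp_path / "sel.vcf"
    sim.sample_vcf(region, str(out), samples_path=str(tmp_path / "s.tsv"))
    text = out.read_text()
    assert "\tSEL\t" in text


def test_retention_failure_budget_raises():
    m = build_demography()
    p = SimParams(seed=1, **SMALL)
    # an impossible initial-frequency window exhausts the retry budget
    ev = SelectionEvent("EUR", 40.0, f0_window=(0.9899, 0.99))
    with pytest.raises(sim.RetryBudgetExhausted):
        run_selected(m, p, ev, max_retries=3)


def test_sample_size_exceeding_population_errors():
    m = single_population_model(10, 20)
    p = SimParams(region_length=1000, sample_size=50, seed=0)
    with pytest.raises(sim.SimulationError):
        run_neutral(m, p)
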