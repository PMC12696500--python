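"""Forward-in-time Wright-Fisher simulation of a recombining region.

Simulates an ``L``-bp region under the four-population demographic model of
:mod:`sweepset.demography`: a long neutral ancestral burn-in, then a forward
phase through all population splits, size changes and migrations.  Selection
on standing variation is modelled by tagging, at a chosen onset time, a
single segregating allele whose frequency in the focal population falls in a
configured window (default 0.10-0.15) and assigning it additive fitness
(1, 1+hs, 1+s).  Selection acts only along the focal population's lineage;
migrants carry the allele neutrally elsewhere.

Mutation follows the infinite-sites model on integer coordinates (collisions
are re-drawn), recombination is uniform along the region with a Poisson
number of crossovers per meiosis.  For efficiency the whole computation can
be rescaled by a factor ``Q`` (sizes and times divided by ``Q``; mutation,
recombination and selection coefficients multiplied by ``Q``), which
preserves the population-scaled parameters 4Nmu, 4Nr and 2Ns.

The engine keeps the haplotypes of one generation as a (2N_total, S) byte
matrix and produces each next generation by gather operations; only the
rare recombinant gametes and new mutations need per-event handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from ._kernels import HAVE_NUMBA, _neutral_phase
from .demography import DemographicModel, DemographyError

__all__ = [
    "SimParams",
    "SelectionEvent",
    "SimulatedRegion",
    "run_neutral",
    "run_selected",
    "rescale",
    "founder_from_freqs",
    "SimulationError",
    "RetryBudgetExhausted",
]

_CLEANUP_INTERVAL = 24


class SimulationError(RuntimeError):
    pass


class RetryBudgetExhausted(SimulationError):
    """No replicate satisfied the tagging/retention conditions."""


class _Discard(Exception):
    """Internal: replicate failed tagging or retention; re-run with new seed."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


@dataclass(frozen=True)
class SimParams:
    """Region-level simulation parameters.

    ``rescale_factor`` Q >= 1 applies the standard speed rescaling at run
    time; ``mutation_rate`` and ``recombination_rate`` are per bp per
    (unscaled) generation.
    """

    region_length: int = 100_000
    mutation_rate: float = 1.25e-8
    recombination_rate: float = 1.25e-8
    rescale_factor: float = 1.0
    sample_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_length < 1_000:
            raise ValueError("region_length must be >= 1,000 bp")
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.rescale_factor < 1:
            raise ValueError("rescale_factor must be >= 1")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")


@dataclass(frozen=True)
class SelectionEvent:
    """Positive selection on a standing variant in one focal population.

    ``s`` is either a fixed selection coefficient or a ``(low, high)`` range
    sampled uniformly per replicate.  ``onset_kya`` is converted to
    generations with the model's generation time; if the focal population
    does not yet exist at onset, selection acts in the ancestral population
    carrying the focal lineage until the split.
    """

    focal_population: str
    onset_kya: float
    s: float | tuple[float, float] = (0.001, 0.005)
    h: float = 0.5
    f0_window: tuple[float, float] = (0.10, 0.15)
    retention_rule: str = "not_lost"

    def __post_init__(self) -> None:
        lo, hi = self.f0_window
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("f0_window must be within (0, 1)")
        if self.retention_rule not in ("not_lost", "polymorphic_at_sampling"):
            raise ValueError(f"unknown retention rule {self.retention_rule!r}")
        s = self.s
        if isinstance(s, tuple):
            if not (0.0 <= s[0] <= s[1]):
                raise ValueError("selection range must satisfy 0 <= low <= high")
        elif s < 0:
            raise ValueError("s must be >= 0")

    def draw_s(self, rng: np.random.Generator) -> float:
        if isinstance(self.s, tuple):
            return float(rng.uniform(self.s[0], self.s[1]))
        return float(self.s)


@dataclass
class SimulatedRegion:
    """Sampled multi-population haplotypes for one simulated region.

    ``haplotypes[pop]`` is a (2 * n_diploids, n_sites) 0/1 matrix with
    phased haplotypes in row pairs; columns are shared across populations,
    sorted by ``positions`` (1-based bp within the region) and polymorphic
    in the pooled sample.  ``selected_site`` indexes the tagged site in
    ``positions`` (``None`` for neutral runs or when the tagged allele is
    monomorphic in the pooled sample; see ``metadata``).
    """

    positions: np.ndarray
    haplotypes: dict[str, np.ndarray]
    selected_site: int | None = None
    trajectory: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def selected_position(self) -> int | None:
        if self.selected_site is None:
            return None
        return int(self.positions[self.selected_site])

    def pooled(self) -> np.ndarray:
        return np.concatenate([self.haplotypes[p] for p in self.haplotypes])

    def dosage(self, pop: str) -> np.ndarray:
        """(n_diploids, n_sites) 0/1/2 genotype dosage matrix for ``pop``."""
        h = self.haplotypes[pop]
        return h[0::2] + h[1::2]


def founder_from_freqs(
    n_diploids: int,
    sites: Iterable[tuple[int, float]],
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Founder haplotypes carrying standing variants at exact frequencies.

    Returns a (2 * n_diploids, n_sites) matrix and the site positions; used
    to initialize a forward run from a controlled state (e.g. one variant at
    frequency 0.5 for drift calibration).
    """
    rng = rng or np.random.default_rng(0)
    sites = list(sites)
    n_hap = 2 * n_diploids
    H = np.zeros((n_hap, len(sites)), dtype=np.uint8)
    positions = []
    for j, (pos, freq) in enumerate(sites):
        k = int(round(freq * n_hap))
        carriers = rng.choice(n_hap, size=k, replace=False)
        H[carriers, j] = 1
        positions.append(int(pos))
    return H, positions


# ---------------------------------------------------------------------------
# schedule: per-(rescaled)-generation sizes of every population
# ---------------------------------------------------------------------------


class _Schedule:
    def __init__(self, model: DemographicModel, q: float):
        self.model = model
        self.q = q
        self.names = list(model.names)
        P = len(self.names)
        self.T = int(round(model.forward_start_gen / q))
        N = np.zeros((self.T + 1, P), dtype=np.int64)
        for g in range(self.T + 1):
            t = (self.T - g) * q
            for j, p in enumerate(model.populations):
                n = p.size_at(t)
                if n > 0:
                    N[g, j] = max(2, int(round(n / q)))
        self.sizes = N
        root = model.root.name
        self.root_idx = self.names.index(root)
        self.parent_idx = {
            j: (self.names.index(p.parent) if p.parent else -1)
            for j, p in enumerate(model.populations)
        }
        self.founding_gen = {}
        for j in range(P):
            alive = np.nonzero(N[:, j])[0]
            if alive.size == 0:
                continue
            g0 = int(alive[0])
            if g0 > 0:
                self.founding_gen[j] = g0
            elif j != self.root_idx:
                raise DemographyError(
                    f"population {self.names[j]} present at the start of the "
                    "forward phase; only the root may be"
                )
        # burn-in pieces: (n_generations, diploid size)
        pieces = []
        epochs = list(model.burnin_epochs)
        for i, (start, size) in enumerate(epochs):
            end = epochs[i + 1][0] if i + 1 < len(epochs) else model.forward_start_gen
            n_gen = int(round((start - end) / q))
            if n_gen > 0:
                pieces.append((n_gen, max(2, int(round(size / q)))))
        self.burnin = pieces
        # migration matrix in model order
        M = np.zeros((P, P))
        for a in range(P):
            for b in range(P):
                if a != b:
                    M[a, b] = model.migration_rate(self.names[a], self.names[b])
        self.mig = M * q
        if np.any(self.mig.sum(axis=1) >= 1.0):
            raise DemographyError("rescaled migration rates exceed 1 per generation")

    @property
    def max_haplotypes(self) -> int:
        m = int(2 * self.sizes.sum(axis=1).max())
        for _, n in self.burnin:
            m = max(m, 2 * n)
        return m


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------


class _Engine:
    """One generation-by-generation run; double-buffered haplotype matrix."""

    def __init__(self, sched: _Schedule, params: SimParams, rng: np.random.Generator):
        self.sched = sched
        self.params = params
        self.rng = rng
        q = params.rescale_factor
        L = params.region_length
        self.L = L
        self.muL = params.mutation_rate * q * L
        self.rL = params.recombination_rate * q * (L - 1)
        cap = 256
        rows = sched.max_haplotypes
        self.A = np.zeros((rows, cap), dtype=np.uint8)
        self.B = np.zeros((rows, cap), dtype=np.uint8)
        self.positions = np.zeros(cap, dtype=np.int64)
        self.live = np.zeros(cap, dtype=bool)
        self.free: list[int] = []
        self.pos_set: set[int] = set()
        self.s_hi = 0
        self._alloc_since = 0
        # current generation layout: per-population (offset, n_diploids)
        self.layout: dict[int, tuple[int, int]] = {}
        self.n_rows = 0
        self.gen_counter = 0
        self.sel_col = -1
        self.track_col = -1

    # -- site bookkeeping ------------------------------------------------
    def _grow(self) -> None:
        cap = self.A.shape[1] * 2
        new_a = np.zeros((self.A.shape[0], cap), dtype=np.uint8)
        n = max(self.n_rows, 1)
        new_a[:n, : self.A.shape[1]] = self.A[:n]  # only A holds live state
        self.A = new_a
        self.B = np.zeros_like(new_a)
        for name, dtype in (("positions", np.int64), ("live", bool)):
            old = getattr(self, name)
            new = np.zeros(cap, dtype=dtype)
            new[: old.size] = old
            setattr(self, name, new)

    def _new_column(self) -> int:
        self._alloc_since += 1
        if self.free:
            return self.free.pop()
        if self.s_hi >= self.A.shape[1]:
            self._grow()
        col = self.s_hi
        self.s_hi += 1
        return col

    def seed_founder(self, haplotypes: np.ndarray, positions: list[int]) -> None:
        n_hap, S = haplotypes.shape
        while S > self.A.shape[1]:
            self._grow()
        self.A[:n_hap, :S] = haplotypes
        self.positions[:S] = positions
        self.live[:S] = True
        self.pos_set = set(int(p) for p in positions)
        self.s_hi = S

    def init_rows(self, pop_idx: int, n_diploids: int) -> None:
        self.layout = {pop_idx: (0, n_diploids)}
        self.n_rows = 2 * n_diploids

    # -- accelerated single-population neutral stretch -------------------
    def run_neutral_phase(
        self, pop_idx: int, sizes: np.ndarray, want_traj: bool = False
    ) -> np.ndarray | None:
        """Advance one isolated neutral population through ``sizes``.

        Dispatches to the numba kernel when available (identical model,
        scalar random stream); otherwise iterates the vectorized step.
        With ``want_traj`` the tracked column's per-generation frequency is
        returned.
        """
        sizes = np.asarray(sizes, dtype=np.int64)
        T = sizes.size
        track = want_traj and self.track_col >= 0
        traj = np.full(T if self.track_col >= 0 else 1, np.nan)
        if T == 0:
            return traj[:0] if track else None
        (off, _) = self.layout[pop_idx]
        if HAVE_NUMBA and off == 0 and len(self.layout) == 1:
            t = 0
            parity = 0
            s_hi, n_rows = self.s_hi, self.n_rows
            free_top = len(self.free)
            free_arr = np.zeros(self.A.shape[1], dtype=np.int64)
            free_arr[:free_top] = self.free
            kernel_track = self.track_col
            while True:
                seed = int(self.rng.integers(1, 2**31 - 1))
                t, s_hi, free_top, n_rows, parity, kernel_track = _neutral_phase(
                    self.A,
                    self.B,
                    self.A.view(np.uint64),
                    self.B.view(np.uint64),
                    self.positions,
                    self.live,
                    free_arr,
                    free_top,
                    s_hi,
                    n_rows,
                    sizes,
                    t,
                    self.L,
                    self.muL,
                    self.rL,
                    kernel_track,
                    traj,
                    parity,
                    seed,
                )
                if t >= T:
                    break
                if parity == 1:  # state lives in B; normalize before growing
                    self.A, self.B = self.B, self.A
                    parity = 0
                self.n_rows = n_rows
                self.s_hi = s_hi
                self._grow()
                new_free = np.zeros(self.A.shape[1], dtype=np.int64)
                new_free[:free_top] = free_arr[:free_top]
                free_arr = new_free
            if parity == 1:
                self.A, self.B = self.B, self.A
            if self.track_col >= 0:
                self.track_col = kernel_track
            self.s_hi = s_hi
            self.n_rows = n_rows
            self.free = [int(c) for c in free_arr[:free_top]]
            self.layout = {pop_idx: (0, int(sizes[-1]))}
            self.gen_counter += T
            self._alloc_since = 0
            idx = np.nonzero(self.live[: self.s_hi])[0]
            self.pos_set = set(int(p) for p in self.positions[idx])
        else:
            for ti in range(T):
                self.step({pop_idx: int(sizes[ti])})
                if track:
                    traj[ti] = self.pop_frequency(pop_idx, self.track_col)
        return traj if track else None

    # -- generation step -------------------------------------------------
    def step(
        self,
        next_sizes: dict[int, int],
        founding: dict[int, int] | None = None,
        sel: tuple[int, float, float] | None = None,
    ) -> None:
        """Produce the next generation.

        ``next_sizes`` maps population index -> diploid count; ``founding``
        maps a population founded this generation to its parent index;
        ``sel`` is (population index, s, h) for viability selection on the
        tagged column among that population's parents.
        """
        rng = self.rng
        founding = founding or {}
        order = sorted(next_sizes)
        offsets = {}
        off = 0
        for j in order:
            offsets[j] = off
            off += 2 * next_sizes[j]
        total_next = off

        single_neutral = (
            sel is None
            and not founding
            and len(order) == 1
            and len(self.layout) == 1
            and order[0] in self.layout
        )
        if single_neutral:
            # one population, no selection: a transmitted gamete is a
            # uniformly chosen parental haplotype (uniform parent x fair
            # haplotype coin), so one draw per gamete suffices
            gidx = rng.integers(0, self.n_rows, total_next)
        else:
            gidx = np.empty(total_next, dtype=np.int64)
            sel_weights: dict[int, np.ndarray] = {}
            if sel is not None and self.sel_col >= 0:
                j, s, h = sel
                if j in self.layout:
                    o, nd = self.layout[j]
                    col = self.A[o : o + 2 * nd, self.sel_col]
                    dos = col[0::2].astype(np.int64) + col[1::2]
                    w = (
                        1.0
                        + np.where(dos == 1, h * s, 0.0)
                        + np.where(dos == 2, s, 0.0)
                    )
                    sel_weights[j] = np.cumsum(w)

            for j in order:
                nd = next_sizes[j]
                base = offsets[j]
                if j in founding:
                    srcs = np.full(nd, founding[j], dtype=np.int64)
                    source_pops = [founding[j]]
                else:
                    rates = self.sched.mig[j]
                    donors = [k for k in self.layout if k != j and rates[k] > 0.0]
                    srcs = np.full(nd, j, dtype=np.int64)
                    if donors:
                        u = rng.random(nd)
                        cum = 0.0
                        for k in donors:
                            pick = (u >= cum) & (u < cum + rates[k])
                            srcs[pick] = k
                            cum += rates[k]
                        source_pops = [j] + [k for k in donors if (srcs == k).any()]
                    else:
                        source_pops = [j]
                for k in source_pops:
                    k = int(k)
                    if len(source_pops) == 1:
                        sel_rows = np.arange(nd)
                    else:
                        sel_rows = np.nonzero(srcs == k)[0]
                    o_src, nd_src = self.layout[k]
                    n_gam = 2 * sel_rows.size
                    if k in sel_weights:
                        cw = sel_weights[k]
                        parents = np.searchsorted(
                            cw, rng.random(n_gam) * cw[-1], side="right"
                        )
                    else:
                        parents = rng.integers(0, nd_src, n_gam)
                    gam = o_src + 2 * parents + rng.integers(0, 2, n_gam)
                    rows = np.empty(n_gam, dtype=np.int64)
                    rows[0::2] = base + 2 * sel_rows
                    rows[1::2] = base + 2 * sel_rows + 1
                    gidx[rows] = gam

        # capacity headroom for this generation's mutations
        n_mut = rng.poisson(self.muL * total_next) if self.muL > 0 else 0
        while self.s_hi + n_mut - len(self.free) > self.A.shape[1]:
            self._grow()

        Bv = self.B[:total_next]
        np.take(self.A, gidx, axis=0, out=Bv)

        # crossovers: Poisson number of breakpoints per transmitted gamete
        if self.rL > 0 and self.s_hi > 0:
            nx = rng.poisson(self.rL * total_next)
            if nx:
                rows_x = rng.integers(0, total_next, nx)
                bps = rng.integers(1, self.L + 1, nx)
                pos = self.positions[: self.s_hi]
                srt = np.sort(rows_x)
                if nx == 1 or not (srt[1:] == srt[:-1]).any():
                    # all gametes distinct: switch to the partner haplotype
                    # beyond each breakpoint in one vectorized pass
                    partner = gidx[rows_x] ^ 1
                    M = pos[None, :] >= bps[:, None]
                    src = self.A[partner, : self.s_hi]
                    dst = Bv[rows_x][:, : self.s_hi]  # fancy indexing copies
                    np.copyto(dst, src, where=M)
                    Bv[rows_x[:, None], np.arange(self.s_hi)[None, :]] = dst
                else:
                    # a gamete hit more than once alternates haplotypes:
                    # take the partner allele where an odd number of
                    # breakpoints lie at or before the site
                    for r in np.unique(rows_x):
                        b = bps[rows_x == r]
                        parity = (pos[None, :] >= b[:, None]).sum(axis=0) % 2 == 1
                        Bv[r, : self.s_hi][parity] = self.A[
                            gidx[int(r)] ^ 1, : self.s_hi
                        ][parity]

        # new mutations (infinite sites on integer coordinates)
        if n_mut:
            mrows = rng.integers(0, total_next, n_mut)
            draws = rng.integers(1, self.L + 1, n_mut)
            new_pos = []
            for i in range(n_mut):
                p = int(draws[i])
                while p in self.pos_set:  # collision: re-draw the position
                    p = int(rng.integers(1, self.L + 1))
                self.pos_set.add(p)
                new_pos.append(p)
            cols = np.array([self._new_column() for _ in range(n_mut)])
            Bv[:, cols] = 0
            Bv[mrows, cols] = 1
            self.positions[cols] = new_pos
            self.live[cols] = True

        self.A, self.B = self.B, self.A
        self.layout = {j: (offsets[j], next_sizes[j]) for j in order}
        self.n_rows = total_next
        self.gen_counter += 1
        # sweep lost/fixed columns periodically, and whenever mutation influx
        # (large growing populations) would otherwise balloon the matrix
        if self.gen_counter % _CLEANUP_INTERVAL == 0 or self._alloc_since >= 192:
            self._cleanup()
            self._alloc_since = 0

    def _cleanup(self) -> None:
        if self.s_hi == 0:
            return
        counts = self.A[: self.n_rows, : self.s_hi].sum(axis=0, dtype=np.int64)
        keep_cols = {self.sel_col, self.track_col}
        dead = self.live[: self.s_hi] & ((counts == 0) | (counts == self.n_rows))
        for c in np.nonzero(dead)[0]:
            c = int(c)
            if c in keep_cols:
                continue
            self.live[c] = False
            self.pos_set.discard(int(self.positions[c]))
            self.free.append(c)
        # compact live columns to the front so gathers stay narrow
        live_idx = np.nonzero(self.live[: self.s_hi])[0]
        if self.s_hi - live_idx.size > 96:
            k = live_idx.size
            self.A[: self.n_rows, :k] = self.A[: self.n_rows, live_idx]
            self.positions[:k] = self.positions[live_idx]
            self.live[:k] = True
            self.live[k : self.s_hi] = False
            if self.sel_col >= 0:
                self.sel_col = int(np.searchsorted(live_idx, self.sel_col))
            if self.track_col >= 0:
                self.track_col = int(np.searchsorted(live_idx, self.track_col))
            self.free = []
            self.s_hi = k

    # -- queries ---------------------------------------------------------
    def pop_frequency(self, pop_idx: int, col: int) -> float:
        o, nd = self.layout[pop_idx]
        if nd == 0:
            return float("nan")
        return float(self.A[o : o + 2 * nd, col].sum()) / (2 * nd)

    def eligible_columns(self, pop_idx: int, f_lo: float, f_hi: float) -> np.ndarray:
        o, nd = self.layout[pop_idx]
        if self.s_hi == 0:
            return np.empty(0, dtype=np.int64)
        counts = self.A[o : o + 2 * nd, : self.s_hi].sum(axis=0, dtype=np.int64)
        freq = counts / (2 * nd)
        ok = self.live[: self.s_hi] & (freq >= f_lo) & (freq <= f_hi)
        return np.nonzero(ok)[0]

    def sample(
        self, pops: Iterable[str], sample_size: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, dict[str, np.ndarray], int | None]:
        """Draw diploid samples, keep pooled-polymorphic columns, sort sites."""
        blocks = {}
        for name in pops:
            j = self.sched.names.index(name)
            if j not in self.layout:
                raise SimulationError(f"population {name} absent at sampling time")
            o, nd = self.layout[j]
            if sample_size > nd:
                raise SimulationError(
                    f"sample_size {sample_size} exceeds population size {nd} "
                    f"of {name}"
                )
            idx = np.sort(rng.choice(nd, size=sample_size, replace=False))
            rows = np.empty(2 * sample_size, dtype=np.int64)
            rows[0::2] = o + 2 * idx
            rows[1::2] = o + 2 * idx + 1
            blocks[name] = self.A[rows, : self.s_hi]
        pooled = np.concatenate(list(blocks.values()))
        counts = pooled.sum(axis=0, dtype=np.int64)
        poly = self.live[: self.s_hi] & (counts > 0) & (counts < pooled.shape[0])
        cols = np.nonzero(poly)[0]
        order = np.argsort(self.positions[cols], kind="stable")
        cols = cols[order]
        positions = self.positions[cols]
        haplotypes = {k: np.ascontiguousarray(v[:, cols]) for k, v in blocks.items()}
        sel_idx = None
        if self.sel_col >= 0:
            hits = np.nonzero(cols == self.sel_col)[0]
            if hits.size:
                sel_idx = int(hits[0])
        return positions.copy(), haplotypes, sel_idx


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------


def _run_forward_kernel(
    eng: "_Engine",
    sched: "_Schedule",
    rng: np.random.Generator,
    g_onset: int,
    lineage: np.ndarray,
    s: float,
    h: float,
    f0: tuple[float, float],
    check_loss: int,
) -> np.ndarray:
    """Drive the numba forward-phase kernel, growing buffers on demand.

    Returns the tagged-allele frequency trajectory (NaN before onset);
    raises :class:`_Discard` when tagging or retention fails.
    """
    from ._kernels import _forward_phase

    P = len(sched.names)
    f_gen = np.full(P, -1, dtype=np.int64)
    f_parent = np.full(P, -1, dtype=np.int64)
    for j, g0 in sched.founding_gen.items():
        f_gen[j] = g0
        f_parent[j] = sched.parent_idx[j]
    traj = np.full(sched.T + 1, np.nan)
    t_start = 1
    parity = 0
    s_hi, n_rows = eng.s_hi, eng.n_rows
    free_top = len(eng.free)
    free_arr = np.zeros(eng.A.shape[1], dtype=np.int64)
    free_arr[:free_top] = eng.free
    sel_col = eng.sel_col
    while True:
        seed = int(rng.integers(1, 2**31 - 1))
        status, g_done, s_hi, free_top, n_rows, parity, sel_col = _forward_phase(
            eng.A,
            eng.B,
            eng.A.view(np.uint64),
            eng.B.view(np.uint64),
            eng.positions,
            eng.live,
            free_arr,
            free_top,
            s_hi,
            n_rows,
            sched.sizes,
            t_start,
            parity,
            f_gen,
            f_parent,
            sched.mig,
            eng.L,
            eng.muL,
            eng.rL,
            g_onset,
            lineage,
            s,
            h,
            f0[0],
            f0[1],
            check_loss,
            sel_col,
            traj,
            seed,
        )
        if status == 3:
            if parity == 1:
                eng.A, eng.B = eng.B, eng.A
                parity = 0
            eng.n_rows = n_rows
            eng.s_hi = s_hi
            eng._grow()
            new_free = np.zeros(eng.A.shape[1], dtype=np.int64)
            new_free[:free_top] = free_arr[:free_top]
            free_arr = new_free
            t_start = g_done
            continue
        break
    if status == 1:
        raise _Discard("no allele in the initial-frequency window")
    if status == 2:
        raise _Discard("selected allele lost")
    if parity == 1:
        eng.A, eng.B = eng.B, eng.A
    eng.s_hi = s_hi
    eng.n_rows = n_rows
    eng.free = [int(c) for c in free_arr[:free_top]]
    eng.sel_col = int(sel_col)
    eng.gen_counter += sched.T
    eng._alloc_since = 0
    layout = {}
    off = 0
    for j in range(P):
        nd = int(sched.sizes[sched.T, j])
        if nd > 0:
            layout[j] = (off, nd)
        off += 2 * nd
    eng.layout = layout
    idx = np.nonzero(eng.live[: eng.s_hi])[0]
    eng.pos_set = set(int(p) for p in eng.positions[idx])
    return traj


def _simulate_once(
    model: DemographicModel,
    params: SimParams,
    rng: np.random.Generator,
    event: SelectionEvent | None = None,
    founder: tuple[np.ndarray, list[int]] | None = None,
    track_position: int | None = None,
) -> SimulatedRegion:
    sched = _Schedule(model, params.rescale_factor)
    eng = _Engine(sched, params, rng)
    q = params.rescale_factor
    T = sched.T
    root = sched.root_idx

    # --- initial state and burn-in (single ancestral population) -------
    if sched.burnin:
        cur = sched.burnin[0][1]
    else:
        cur = int(sched.sizes[0, root]) if T > 0 else int(round(model.root.size / q))
    if founder is not None:
        H0, pos0 = founder
        if H0.shape[0] != 2 * cur:
            raise SimulationError(
                f"founder has {H0.shape[0]} haplotypes, expected {2 * cur}"
            )
        eng.seed_founder(H0, pos0)
    eng.init_rows(root, cur)
    if track_position is not None:
        hits = np.nonzero(eng.positions[: eng.s_hi] == track_position)[0]
        if hits.size == 0:
            raise SimulationError("track_position not among founder sites")
        eng.track_col = int(hits[0])
    if sched.burnin:
        burnin_sizes = np.concatenate(
            [np.full(n_gen, size, dtype=np.int64) for n_gen, size in sched.burnin]
        )
        eng.run_neutral_phase(root, burnin_sizes)

    # --- forward phase --------------------------------------------------
    sel_state = None
    trajectory: list[float] = []
    track_traj: list[float] = []
    g_onset = None
    if event is not None:
        onset_gen = model.kya_to_gen(event.onset_kya)
        if onset_gen > model.forward_start_gen:
            raise SimulationError(
                "selection onset predates the forward phase; extend the model"
            )
        g_onset = T - int(round(onset_gen / q))
        if not (0 < g_onset <= T):
            raise SimulationError(
                f"onset {event.onset_kya} kya does not fall inside the forward phase"
            )
        s_draw = event.draw_s(rng) * q
        lineage = [
            sched.names.index(model.lineage_at(event.focal_population, (T - g) * q))
            for g in range(T + 1)
        ]

    def record(g: int) -> None:
        if eng.track_col >= 0:
            track_traj.append(eng.pop_frequency(root, eng.track_col))
        if sel_state is not None:
            j = lineage[g]
            f = eng.pop_frequency(j, eng.sel_col)
            trajectory.append(f)
            if event.retention_rule == "not_lost" and f == 0.0:
                raise _Discard("selected allele lost")

    if eng.track_col >= 0:
        track_traj.append(eng.pop_frequency(root, eng.track_col))

    general_from = 1
    if event is None and len(sched.names) == 1 and T > 0:
        # isolated neutral population: run the whole forward phase through
        # the accelerated single-population path
        traj = eng.run_neutral_phase(
            root, sched.sizes[1:, root], want_traj=eng.track_col >= 0
        )
        if traj is not None:
            track_traj.extend(float(x) for x in traj)
        general_from = T + 1  # nothing left for the general loop
    elif HAVE_NUMBA and T > 0 and eng.track_col < 0:
        sel_traj = _run_forward_kernel(
            eng,
            sched,
            rng,
            g_onset=-1 if g_onset is None else g_onset,
            lineage=(
                np.full(T + 1, -1, dtype=np.int64)
                if event is None
                else np.asarray(lineage, dtype=np.int64)
            ),
            s=s_draw if event is not None else 0.0,
            h=event.h if event is not None else 0.5,
            f0=event.f0_window if event is not None else (0.0, 1.0),
            check_loss=int(
                event is not None and event.retention_rule == "not_lost"
            ),
        )
        if event is not None:
            sel_state = (s_draw, event.h)
            trajectory = [float(x) for x in sel_traj[g_onset:]]
        general_from = T + 1  # nothing left for the general loop

    for g in range(general_from, T + 1):
        next_sizes = {
            j: int(n) for j, n in enumerate(sched.sizes[g]) if n > 0
        }
        founding = {
            j: sched.parent_idx[j]
            for j, g0 in sched.founding_gen.items()
            if g0 == g
        }
        sel = None
        if sel_state is not None:
            j = lineage[g - 1]
            sel = (j, sel_state[0], sel_state[1])
        eng.step(next_sizes, founding=founding, sel=sel)
        if g_onset is not None and g == g_onset and sel_state is None:
            j = lineage[g]
            elig = eng.eligible_columns(j, *event.f0_window)
            if elig.size == 0:
                raise _Discard("no allele in the initial-frequency window")
            eng.sel_col = int(rng.choice(elig))
            sel_state = (s_draw, event.h)
            trajectory.append(eng.pop_frequency(j, eng.sel_col))
            if eng.track_col >= 0:
                track_traj.append(eng.pop_frequency(root, eng.track_col))
            continue
        record(g)

    fixed_flag = False
    if sel_state is not None:
        j = lineage[T]
        f_final = eng.pop_frequency(j, eng.sel_col)
        if event.retention_rule == "polymorphic_at_sampling" and not (
            0.0 < f_final < 1.0
        ):
            raise _Discard("selected allele not polymorphic at sampling")
        if event.retention_rule == "not_lost" and f_final == 0.0:
            raise _Discard("selected allele lost")
        fixed_flag = f_final == 1.0

    positions, haplotypes, sel_idx = eng.sample(
        model.sampled, params.sample_size, rng
    )
    meta = {
        "seed": params.seed,
        "rescale_factor": q,
        "region_length": params.region_length,
        "neutral": event is None,
    }
    if event is not None:
        meta.update(
            {
                "focal_population": event.focal_population,
                "onset_kya": event.onset_kya,
                "s": s_draw / q,
                "h": event.h,
                "selected_fixed_in_focal": fixed_flag,
                "selected_position": int(eng.positions[eng.sel_col]),
                "selected_in_sample": sel_idx is not None,
            }
        )
    if track_position is not None:
        meta["tracked_trajectory"] = np.asarray(track_traj)
    return SimulatedRegion(
        positions=positions,
        haplotypes=haplotypes,
        selected_site=sel_idx,
        trajectory=np.asarray(trajectory) if trajectory else None,
        metadata=meta,
    )


def run_neutral(
    model: DemographicModel,
    params: SimParams,
    founder: tuple[np.ndarray, list[int]] | None = None,
    track_position: int | None = None,
) -> SimulatedRegion:
    """Simulate one neutral region; reproducible for a given ``params.seed``."""
    rng = np.random.default_rng([params.seed, 0x6E65])
    return _simulate_once(
        model, params, rng, event=None, founder=founder, track_position=track_position
    )


def run_selected(
    model: DemographicModel,
    params: SimParams,
    event: SelectionEvent,
    max_retries: int = 200,
) -> SimulatedRegion:
    """Simulate one region under selection on standing variation.

    Replicates where no allele falls in the initial-frequency window at
    onset, or where the tagged allele fails the retention rule, are
    discarded and re-simulated with a fresh seed stream (bounded by
    ``max_retries``); the number of attempts is recorded in the metadata.
    """
    for attempt in range(max_retries):
        rng = np.random.default_rng([params.seed, 0x73656C, attempt])
        try:
            region = _simulate_once(model, params, rng, event=event)
        except _Discard:
            continue
        region.metadata["attempts"] = attempt + 1
        return region
    raise RetryBudgetExhausted(
        f"no successful replicate in {max_retries} attempts; eligible alleles "
        "may be vanishingly rare in this parameter regime"
    )


def rescale(
    model: DemographicModel,
    params: SimParams,
    q: float,
    event: SelectionEvent | None = None,
):
    """Materialize the speed rescaling: N/q, times/q, mu*q, r*q, s*q.

    Returns ``(model', params')`` (plus ``event'`` when given) such that the
    population-scaled parameters 4Nmu, 4Nr and 2Ns are preserved within
    rounding.  The engine applies the same transformation internally when
    ``params.rescale_factor`` > 1; this explicit form exists for inspection
    and for running pre-scaled configurations.
    """
    model2 = model.rescaled(q)
    params2 = replace(
        params,
        mutation_rate=params.mutation_rate * q,
        recombination_rate=params.recombination_rate * q,
        rescale_factor=1.0,
    )
    if event is None:
        return model2, params2
    s = event.s
    s2 = (s[0] * q, s[1] * q) if isinstance(s, tuple) else s * q
    return model2, params2, replace(event, s=s2)


def sample_vcf(
    region: SimulatedRegion,
    path: str,
    samples_path: str | None = None,
    chrom: str = "sim1",
) -> None:
    """Write the region as a phased VCF 4.2 plus a sample-population TSV."""
    from .variant_io import write_region_vcf

    write_region_vcf(region, path, samples_path=samples_path, chrom=chrom)
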