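"""Optional numba acceleration for single-population neutral phases.

The ancestral burn-in (and any other stretch with one population, no
selection and no migration) dominates run time; this kernel advances it
generation by generation with the exact same model as the numpy engine:
uniform parental haplotype per gamete, per-gamete Poisson crossovers with
haplotype alternation, Poisson infinite-sites mutation with collision
re-draws, and periodic sweeping/compaction of lost and fixed columns.
Row copies go through word-width views of the byte matrix so they
vectorize.

If numba is unavailable the engine silently falls back to its vectorized
numpy path; results differ only through the random streams.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _neutral_phase(
    A,
    B,
    A64,
    B64,
    positions,
    live,
    free,
    free_top,
    s_hi,
    n_rows,
    sizes,
    t_start,
    L,
    muL,
    rL,
    track_col,
    traj,
    parity,
    seed,
):
    """Advance a single neutral population through ``sizes[t_start:]``.

    Returns (t_done, s_hi, free_top, n_rows, parity, track_col).  Stops
    early (t_done < len(sizes)) when column capacity is exhausted so the
    caller can grow the buffers and resume.
    """
    np.random.seed(seed)
    cap = A.shape[1]
    T = sizes.shape[0]
    counts = np.zeros(cap, dtype=np.int64)
    zero_mask = np.zeros(cap, dtype=np.uint8)
    gsrc = np.zeros(A.shape[0], dtype=np.int64)
    sweep_phase = 0
    alloc_since = 0
    for t in range(t_start, T):
        if parity == 0:
            cur, nxt = A, B
            cur64, nxt64 = A64, B64
        else:
            cur, nxt = B, A
            cur64, nxt64 = B64, A64
        nh = 2 * sizes[t]
        if s_hi + int(3.0 * muL * nh) + 8 - free_top > cap:
            return t, s_hi, free_top, n_rows, parity, track_col
        w = (s_hi + 7) // 8
        for i in range(nh):
            src = np.random.randint(0, n_rows)
            gsrc[i] = src
            nxt64[i, :w] = cur64[src, :w]
        # crossovers as Poisson-thinned events over all transmitted gametes
        if rL > 0.0 and s_hi > 0:
            nx = np.random.poisson(rL * nh)
            if nx > 0:
                rx = np.empty(nx, dtype=np.int64)
                bx = np.empty(nx, dtype=np.int64)
                for e in range(nx):
                    rx[e] = np.random.randint(0, nh)
                    bx[e] = np.random.randint(1, L + 1)
                done = np.zeros(nx, dtype=np.uint8)
                for e in range(nx):
                    if done[e] == 1:
                        continue
                    row = rx[e]
                    kk = 0
                    for e2 in range(e, nx):
                        if rx[e2] == row:
                            done[e2] = 1
                            kk += 1
                    bps = np.empty(kk, dtype=np.int64)
                    i = 0
                    for e2 in range(e, nx):
                        if rx[e2] == row:
                            bps[i] = bx[e2]
                            i += 1
                    partner = gsrc[row] ^ 1
                    for c in range(s_hi):
                        cnt = 0
                        for q in range(kk):
                            if positions[c] >= bps[q]:
                                cnt += 1
                        if cnt % 2 == 1:
                            nxt[row, c] = cur[partner, c]
        if muL > 0.0:
            nm = np.random.poisson(muL * nh)
            for e in range(nm):
                row = np.random.randint(0, nh)
                ok = False
                p = 0
                while not ok:
                    p = np.random.randint(1, L + 1)
                    ok = True
                    for c in range(s_hi):
                        if live[c] and positions[c] == p:
                            ok = False
                            break
                if free_top > 0:
                    # freed columns were zeroed when swept
                    free_top -= 1
                    col = free[free_top]
                else:
                    col = s_hi
                    s_hi += 1
                    alloc_since += 1
                    for r in range(nh):
                        nxt[r, col] = 0
                nxt[row, col] = 1
                positions[col] = p
                live[col] = True
        n_rows = nh
        parity = 1 - parity
        sweep_phase += 1
        if sweep_phase >= 24 or alloc_since >= 192:
            sweep_phase = 0
            alloc_since = 0
            # row-major column counts (cache-friendly)
            for c in range(s_hi):
                counts[c] = 0
            for r in range(nh):
                row_v = nxt[r]
                for c in range(s_hi):
                    counts[c] += row_v[c]
            live_cnt = 0
            any_fixed = False
            for c in range(s_hi):
                if live[c]:
                    if c == track_col:
                        live_cnt += 1
                        continue
                    if counts[c] == 0 or counts[c] == nh:
                        live[c] = False
                        free[free_top] = c
                        free_top += 1
                        if counts[c] == nh:
                            zero_mask[c] = 1
                            any_fixed = True
                    else:
                        live_cnt += 1
            if any_fixed:
                for r in range(nh):
                    row_v = nxt[r]
                    for c in range(s_hi):
                        if zero_mask[c] == 1:
                            row_v[c] = 0
                for c in range(s_hi):
                    zero_mask[c] = 0
            if s_hi - live_cnt > 96:
                # left-pack live columns, row-major
                for r in range(nh):
                    row_v = nxt[r]
                    nc = 0
                    for c in range(s_hi):
                        if live[c]:
                            row_v[nc] = row_v[c]
                            nc += 1
                new_c = 0
                for c in range(s_hi):
                    if live[c]:
                        positions[new_c] = positions[c]
                        if c == track_col:
                            track_col = new_c
                        new_c += 1
                for c in range(new_c):
                    live[c] = True
                for c in range(new_c, s_hi):
                    live[c] = False
                s_hi = new_c
                free_top = 0
        if track_col >= 0:
            cnt = 0
            for r in range(nh):
                cnt += nxt[r, track_col]
            traj[t] = cnt / nh
    return T, s_hi, free_top, n_rows, parity, track_col


@njit(cache=True)
def _forward_phase(
    A,
    B,
    A64,
    B64,
    positions,
    live,
    free,
    free_top,
    s_hi,
    n_rows,
    sizes,
    t_start,
    parity,
    f_gen,
    f_parent,
    mig,
    L,
    muL,
    rL,
    g_onset,
    lineage,
    s,
    h,
    f0_lo,
    f0_hi,
    check_loss,
    sel_col,
    traj,
    seed,
):
    """Advance the multi-population forward phase from generation t_start.

    ``sizes`` is (T+1, P); generation g is produced from generation g-1.
    ``lineage[g]`` is the population index carrying the focal lineage (-1
    without a selection event); at ``g_onset`` a live column with frequency
    inside [f0_lo, f0_hi] in the lineage population is tagged and from then
    on parents in the lineage population are fitness-weighted (1, 1+hs,
    1+s).  ``traj[g]`` records the tagged-allele frequency.

    Returns (status, g_done, s_hi, free_top, n_rows, parity, sel_col) with
    status 0 = finished, 1 = no eligible allele at onset, 2 = allele lost,
    3 = column capacity exhausted (grow buffers and resume at g_done).
    """
    np.random.seed(seed)
    cap = A.shape[1]
    T = sizes.shape[0] - 1
    P = sizes.shape[1]
    cur_off = np.zeros(P, dtype=np.int64)
    nxt_off = np.zeros(P, dtype=np.int64)
    cumw = np.zeros(A.shape[0] // 2 + 1, dtype=np.float64)
    gsrc = np.zeros(A.shape[0], dtype=np.int64)
    elig = np.zeros(cap, dtype=np.int64)
    counts = np.zeros(cap, dtype=np.int64)
    zero_mask = np.zeros(cap, dtype=np.uint8)
    sweep_phase = 0
    alloc_since = 0
    for g in range(t_start, T + 1):
        if parity == 0:
            cur, nxt = A, B
            cur64, nxt64 = A64, B64
        else:
            cur, nxt = B, A
            cur64, nxt64 = B64, A64
        off = 0
        for j in range(P):
            cur_off[j] = off
            off += 2 * sizes[g - 1, j]
        total_next = 0
        for j in range(P):
            nxt_off[j] = total_next
            total_next += 2 * sizes[g, j]
        if s_hi + int(3.0 * muL * total_next) + 8 - free_top > cap:
            return 3, g, s_hi, free_top, n_rows, parity, sel_col
        w = (s_hi + 7) // 8
        # fitness weights among the lineage population's parents
        have_w = False
        jw = -1
        tot_w = 0.0
        if sel_col >= 0 and g_onset >= 0 and g - 1 >= g_onset:
            jw = lineage[g - 1]
            if jw >= 0 and sizes[g - 1, jw] > 0:
                o = cur_off[jw]
                nd_w = sizes[g - 1, jw]
                tot_w = 0.0
                for d in range(nd_w):
                    dos = cur[o + 2 * d, sel_col] + cur[o + 2 * d + 1, sel_col]
                    if dos == 1:
                        wv = 1.0 + h * s
                    elif dos == 2:
                        wv = 1.0 + s
                    else:
                        wv = 1.0
                    tot_w += wv
                    cumw[d] = tot_w
                have_w = True
        for j in range(P):
            nd = sizes[g, j]
            if nd == 0:
                continue
            base = nxt_off[j]
            founded_now = f_gen[j] == g
            for d in range(nd):
                if founded_now:
                    src_pop = f_parent[j]
                else:
                    src_pop = j
                    u = np.random.random()
                    acc = 0.0
                    for k in range(P):
                        if k != j and sizes[g - 1, k] > 0 and mig[j, k] > 0.0:
                            acc += mig[j, k]
                            if u < acc:
                                src_pop = k
                                break
                nd_src = sizes[g - 1, src_pop]
                for gam in range(2):
                    if have_w and src_pop == jw:
                        uu = np.random.random() * tot_w
                        lo = 0
                        hi_i = nd_src
                        while lo < hi_i:
                            mid = (lo + hi_i) // 2
                            if cumw[mid] <= uu:
                                lo = mid + 1
                            else:
                                hi_i = mid
                        par = lo
                        if par >= nd_src:
                            par = nd_src - 1
                    else:
                        par = np.random.randint(0, nd_src)
                    src_row = (
                        cur_off[src_pop] + 2 * par + np.random.randint(0, 2)
                    )
                    row = base + 2 * d + gam
                    nxt64[row, :w] = cur64[src_row, :w]
                    gsrc[row] = src_row
        # crossovers (Poisson-thinned events over all transmitted gametes)
        if rL > 0.0 and s_hi > 0:
            nx = np.random.poisson(rL * total_next)
            if nx > 0:
                rx = np.empty(nx, dtype=np.int64)
                bx = np.empty(nx, dtype=np.int64)
                for e in range(nx):
                    rx[e] = np.random.randint(0, total_next)
                    bx[e] = np.random.randint(1, L + 1)
                done = np.zeros(nx, dtype=np.uint8)
                for e in range(nx):
                    if done[e] == 1:
                        continue
                    row = rx[e]
                    kk = 0
                    for e2 in range(e, nx):
                        if rx[e2] == row:
                            done[e2] = 1
                            kk += 1
                    bps = np.empty(kk, dtype=np.int64)
                    i = 0
                    for e2 in range(e, nx):
                        if rx[e2] == row:
                            bps[i] = bx[e2]
                            i += 1
                    partner = gsrc[row] ^ 1
                    for c in range(s_hi):
                        cnt = 0
                        for q in range(kk):
                            if positions[c] >= bps[q]:
                                cnt += 1
                        if cnt % 2 == 1:
                            nxt[row, c] = cur[partner, c]
        # mutations
        if muL > 0.0:
            nm = np.random.poisson(muL * total_next)
            for e in range(nm):
                row = np.random.randint(0, total_next)
                ok = False
                p = 0
                while not ok:
                    p = np.random.randint(1, L + 1)
                    ok = True
                    for c in range(s_hi):
                        if live[c] and positions[c] == p:
                            ok = False
                            break
                if free_top > 0:
                    # freed columns were zeroed when swept
                    free_top -= 1
                    col = free[free_top]
                else:
                    col = s_hi
                    s_hi += 1
                    alloc_since += 1
                    for r in range(total_next):
                        nxt[r, col] = 0
                nxt[row, col] = 1
                positions[col] = p
                live[col] = True
        n_rows = total_next
        parity = 1 - parity
        # tag a standing variant at onset
        if g_onset >= 0 and g == g_onset and sel_col < 0:
            j0 = lineage[g]
            o = nxt_off[j0]
            nh0 = 2 * sizes[g, j0]
            n_elig = 0
            for c in range(s_hi):
                if live[c]:
                    cnt = 0
                    for r in range(o, o + nh0):
                        cnt += nxt[r, c]
                    fr = cnt / nh0
                    if f0_lo <= fr <= f0_hi:
                        elig[n_elig] = c
                        n_elig += 1
            if n_elig == 0:
                return 1, g, s_hi, free_top, n_rows, parity, sel_col
            sel_col = elig[np.random.randint(0, n_elig)]
        # trajectory and loss check in the lineage population
        if sel_col >= 0 and g >= g_onset:
            jl = lineage[g]
            o = nxt_off[jl]
            nh0 = 2 * sizes[g, jl]
            cnt = 0
            for r in range(o, o + nh0):
                cnt += nxt[r, sel_col]
            fr = cnt / nh0
            traj[g] = fr
            if check_loss == 1 and fr == 0.0:
                return 2, g, s_hi, free_top, n_rows, parity, sel_col
        sweep_phase += 1
        if sweep_phase >= 24 or alloc_since >= 192:
            sweep_phase = 0
            alloc_since = 0
            for c in range(s_hi):
                counts[c] = 0
            for r in range(total_next):
                row_v = nxt[r]
                for c in range(s_hi):
                    counts[c] += row_v[c]
            live_cnt = 0
            any_fixed = False
            for c in range(s_hi):
                if live[c]:
                    if c == sel_col:
                        live_cnt += 1
                        continue
                    if counts[c] == 0 or counts[c] == total_next:
                        live[c] = False
                        free[free_top] = c
                        free_top += 1
                        if counts[c] == total_next:
                            zero_mask[c] = 1
                            any_fixed = True
                    else:
                        live_cnt += 1
            if any_fixed:
                for r in range(total_next):
                    row_v = nxt[r]
                    for c in range(s_hi):
                        if zero_mask[c] == 1:
                            row_v[c] = 0
                for c in range(s_hi):
                    zero_mask[c] = 0
            if s_hi - live_cnt > 96:
                for r in range(total_next):
                    row_v = nxt[r]
                    nc = 0
                    for c in range(s_hi):
                        if live[c]:
                            row_v[nc] = row_v[c]
                            nc += 1
                new_c = 0
                for c in range(s_hi):
                    if live[c]:
                        positions[new_c] = positions[c]
                        if c == sel_col:
                            sel_col = new_c
                        new_c += 1
                for c in range(new_c):
                    live[c] = True
                for c in range(new_c, s_hi):
                    live[c] = False
                s_hi = new_c
                free_top = 0
    return 0, T + 1, s_hi, free_top, n_rows, parity, sel_col
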