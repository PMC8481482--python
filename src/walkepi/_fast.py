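"""Numba-compiled inner loops of the lattice epidemic.

Private module: the public API lives in :mod:`walkepi.simulator`.  The jump
formula here must stay identical to :mod:`walkepi.kernel` (same inverse-CDF
sampler, same dual-lattice snapping); the test suite cross-checks the two
paths statistically.

Site bookkeeping uses a hash map from a packed 64-bit cell key to a status
byte, so the lattice is unbounded and memory scales with the number of
*touched* sites only.  Randomness is numba's own Mersenne-Twister state,
seeded per call; every entry point takes an explicit 31-bit seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit, types
from numba.typed import Dict

# site status codes (shared with simulator.py / snapshot rasters)
VISITED = np.uint8(1)
REMOVED = np.uint8(2)

# outcome codes
DIED_OUT = 0
CENSORED_ACTIVE = 1

_TWO_PI = 2.0 * np.pi


@njit(cache=True, inline="always")
def _jump_displacement():
    """One kernel draw: integer landed-cell displacement (dx, dy)."""
    u = 1.0 - np.random.random()  # (0, 1]
    r = (3.0 * u) ** (-1.0 / 3.0)
    theta = _TWO_PI * np.random.random()
    dx = np.int64(np.floor(0.5 + r * np.sin(theta)))
    dy = np.int64(np.floor(0.5 + r * np.cos(theta)))
    return dx, dy


@njit(cache=True, inline="always")
def _key(x, y):
    """Pack a cell (|coord| < 2**31) into one int64 hash key."""
    return (x << np.int64(32)) ^ (y & np.int64(0xFFFFFFFF))


@njit(cache=True)
def _unpack_keys(keys):
    """Inverse of :func:`_key` for an array of keys."""
    n = keys.shape[0]
    xs = np.empty(n, np.int64)
    ys = np.empty(n, np.int64)
    for i in range(n):
        x = keys[i] >> np.int64(32)
        y = keys[i] & np.int64(0xFFFFFFFF)
        if y >= np.int64(0x80000000):
            y -= np.int64(0x100000000)
        xs[i] = x
        ys[i] = y
    return xs, ys


@njit(cache=True)
def run_epidemic(
    seed,
    tau,
    p1,
    p2,
    two_region,
    boundary_y,
    start_y,
    max_time,
    max_removed,
):
    """Full epidemic dynamics from a single index case at (0, start_y).

    Synchronous sweeps: every walker alive at the start of a step jumps once
    (roster shuffled each step); a walker spawned during step t first jumps
    at step t+1 and lives for exactly ``tau`` jumps of its own.  A landing
    on a non-removed site triggers a Bernoulli(p) infection trial with p
    taken from the landing cell's region (uniform field: p1 everywhere;
    two-region field: p1 for y <= boundary_y, p2 above).  Infection marks
    the site removed and spawns a walker there; failure marks it visited.

    Returns per-step traces (lengths n_steps+1, index = time):
      active[t], removed[t], rg_removed[t], rg_active[t],
      removed_r1[t], removed_r2[t],
    plus outcome code, final site keys/status arrays and the final roster
    (cur_x, cur_y, birth_x, birth_y, steps_remaining).
    """
    np.random.seed(seed)
    status = Dict.empty(types.int64, types.uint8)

    cap = 256
    wx = np.empty(cap, np.int64)
    wy = np.empty(cap, np.int64)
    wbx = np.empty(cap, np.int64)
    wby = np.empty(cap, np.int64)
    wleft = np.empty(cap, np.int64)
    n_w = 1
    wx[0] = 0
    wy[0] = start_y
    wbx[0] = 0
    wby[0] = start_y
    wleft[0] = tau

    status[_key(np.int64(0), np.int64(start_y))] = REMOVED
    removed = 1
    # running sums over removed sites for the gyration radius
    sx = 0.0
    sy = float(start_y)
    s2 = float(start_y) * float(start_y)
    removed_r1 = 1 if start_y <= boundary_y else 0
    removed_r2 = 1 - removed_r1

    tr_active = np.zeros(max_time + 1, np.int64)
    tr_removed = np.zeros(max_time + 1, np.int64)
    tr_rg = np.zeros(max_time + 1, np.float64)
    tr_rg_active = np.zeros(max_time + 1, np.float64)
    tr_r1 = np.zeros(max_time + 1, np.int64)
    tr_r2 = np.zeros(max_time + 1, np.int64)

    tr_active[0] = 1
    tr_removed[0] = 1
    tr_r1[0] = removed_r1
    tr_r2[0] = removed_r2

    outcome = DIED_OUT
    t = 0
    while t < max_time:
        if n_w == 0:
            break
        t += 1
        n0 = n_w  # walkers eligible this step; later spawns wait a step
        order = np.arange(n0)
        np.random.shuffle(order)
        for oi in range(n0):
            i = order[oi]
            dx, dy = _jump_displacement()
            x = wx[i] + dx
            y = wy[i] + dy
            wx[i] = x
            wy[i] = y
            k = _key(x, y)
            st = status.get(k, np.uint8(0))
            if st != REMOVED:
                p = p1
                if two_region and y > boundary_y:
                    p = p2
                if np.random.random() < p:
                    status[k] = REMOVED
                    removed += 1
                    fx = float(x)
                    fy = float(y)
                    sx += fx
                    sy += fy
                    s2 += fx * fx + fy * fy
                    if y <= boundary_y:
                        removed_r1 += 1
                    else:
                        removed_r2 += 1
                    if n_w == cap:  # grow roster
                        cap *= 2
                        wx2 = np.empty(cap, np.int64)
                        wy2 = np.empty(cap, np.int64)
                        wbx2 = np.empty(cap, np.int64)
                        wby2 = np.empty(cap, np.int64)
                        wleft2 = np.empty(cap, np.int64)
                        wx2[:n_w] = wx[:n_w]
                        wy2[:n_w] = wy[:n_w]
                        wbx2[:n_w] = wbx[:n_w]
                        wby2[:n_w] = wby[:n_w]
                        wleft2[:n_w] = wleft[:n_w]
                        wx = wx2
                        wy = wy2
                        wbx = wbx2
                        wby = wby2
                        wleft = wleft2
                    wx[n_w] = x
                    wy[n_w] = y
                    wbx[n_w] = x
                    wby[n_w] = y
                    wleft[n_w] = tau
                    n_w += 1
                elif st == np.uint8(0):
                    status[k] = VISITED
            wleft[i] -= 1
        # retire expired walkers (swap-remove)
        i = 0
        while i < n_w:
            if wleft[i] == 0:
                n_w -= 1
                wx[i] = wx[n_w]
                wy[i] = wy[n_w]
                wbx[i] = wbx[n_w]
                wby[i] = wby[n_w]
                wleft[i] = wleft[n_w]
            else:
                i += 1

        tr_active[t] = n_w
        tr_removed[t] = removed
        tr_r1[t] = removed_r1
        tr_r2[t] = removed_r2
        mx = sx / removed
        my = sy / removed
        var = s2 / removed - mx * mx - my * my
        tr_rg[t] = np.sqrt(var) if var > 0.0 else 0.0
        # gyration radius of the active set (birth sites of live walkers)
        if n_w > 0:
            bx = 0.0
            by = 0.0
            b2 = 0.0
            for j in range(n_w):
                fx = float(wbx[j])
                fy = float(wby[j])
                bx += fx
                by += fy
                b2 += fx * fx + fy * fy
            bx /= n_w
            by /= n_w
            var_a = b2 / n_w - bx * bx - by * by
            tr_rg_active[t] = np.sqrt(var_a) if var_a > 0.0 else 0.0
        if removed >= max_removed:
            outcome = CENSORED_ACTIVE
            break

    if n_w > 0:
        outcome = CENSORED_ACTIVE

    n_steps = t
    n_sites = len(status)
    site_keys = np.empty(n_sites, np.int64)
    site_status = np.empty(n_sites, np.uint8)
    j = 0
    for k, v in status.items():
        site_keys[j] = k
        site_status[j] = v
        j += 1

    return (
        tr_active[: n_steps + 1],
        tr_removed[: n_steps + 1],
        tr_rg[: n_steps + 1],
        tr_rg_active[: n_steps + 1],
        tr_r1[: n_steps + 1],
        tr_r2[: n_steps + 1],
        outcome,
        site_keys,
        site_status,
        wx[:n_w].copy(),
        wy[:n_w].copy(),
        wbx[:n_w].copy(),
        wby[:n_w].copy(),
        wleft[:n_w].copy(),
    )


@njit(cache=True)
def index_case_counts(seed, tau, p1, p2, two_region, boundary_y, start_y, n_real):
    """Secondary infections by the index walker alone, per realization.

    The index walker takes ``tau`` jumps; every landing on a site it has not
    already infected (its start site counts as removed) triggers a
    Bernoulli(p) trial.  Secondary walkers are not simulated.  Returns the
    per-realization infection counts split by region (region 2 counts are
    zero for a uniform field).
    """
    np.random.seed(seed)
    counts1 = np.zeros(n_real, np.int64)
    counts2 = np.zeros(n_real, np.int64)
    hit_x = np.empty(tau + 1, np.int64)
    hit_y = np.empty(tau + 1, np.int64)
    for i in range(n_real):
        x = np.int64(0)
        y = np.int64(start_y)
        hit_x[0] = x
        hit_y[0] = y
        n_hit = 1
        for _ in range(tau):
            dx, dy = _jump_displacement()
            x += dx
            y += dy
            infected_before = False
            for h in range(n_hit):
                if hit_x[h] == x and hit_y[h] == y:
                    infected_before = True
                    break
            if infected_before:
                continue
            p = p1
            if two_region and y > boundary_y:
                p = p2
            if np.random.random() < p:
                hit_x[n_hit] = x
                hit_y[n_hit] = y
                n_hit += 1
                if y <= boundary_y:
                    counts1[i] += 1
                else:
                    counts2[i] += 1
    return counts1, counts2
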