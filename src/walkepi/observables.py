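"""Measurement layer: phase diagrams, cluster geometry and scaling fits.

Everything here consumes the simulator's outputs (traces and lattice
states) and produces the summary statistics of the model's behavior:

* the *phase variable* — fraction of realizations that die out — mapped
  over a (p, tau) grid, with the phase boundary extracted per tau as the
  p where the die-out fraction crosses 0.5 and summarized by a power law
  ``p_boundary = a tau**b``;
* cluster geometry of the removed set: radius of gyration, spatial
  autocorrelation, surface-site count;
* power-law growth fits ``count ~ Rg**exponent`` for the removed and
  active sets (the latter probing the directed-percolation slice
  dimension);
* the index-case R0 table over a (p, tau) grid.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import fftconvolve

from . import simulator, theory
from .simulator import EpidemicTrace, LatticeState, SimConfig, child_seeds

__all__ = [
    "phase_variable",
    "PhaseDiagram",
    "phase_diagram",
    "BoundaryFit",
    "phase_boundary",
    "radius_of_gyration",
    "spatial_autocorrelation",
    "surface_sites",
    "ScalingFit",
    "growth_scaling_fit",
    "collect_surviving_traces",
    "r0_table",
]


# ---------------------------------------------------------------- phase


def phase_variable(
    p: float,
    tau: int,
    n_realizations: int,
    seed: int,
    max_time: int | None = None,
    max_removed: int = 25_000,
) -> tuple[float, float]:
    """Fraction of full-dynamics realizations that die out, with std. error.

    Censored realizations (caps hit with walkers still active) count as
    spreading.  Returns ``(fraction, binomial standard error)``.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    cfg = SimConfig.uniform(p, tau, max_time=max_time, max_removed=max_removed)
    seeds = child_seeds(seed, n_realizations)
    died = 0
    for s in seeds:
        died += simulator.run(cfg, seed=int(s), keep_state=False).died_out
    frac = died / n_realizations
    return frac, math.sqrt(frac * (1.0 - frac) / n_realizations)


@dataclass
class PhaseDiagram:
    """Grid of die-out fractions over (p, tau)."""

    table: pd.DataFrame  # columns: tau, p, n, phase, stderr
    max_removed: int = 25_000

    def rows_for_tau(self, tau: int) -> pd.DataFrame:
        return self.table[self.table["tau"] == tau].sort_values("p")


def phase_diagram(
    p_grid,
    tau_grid,
    n_realizations: int,
    seed: int,
    max_time: int | None = None,
    max_removed: int = 25_000,
) -> PhaseDiagram:
    """Estimate the phase variable over a (p, tau) grid.

    ``p_grid`` is either a single sequence of p values used for every tau,
    or a mapping ``tau -> sequence of p``.
    """
    rows = []
    n_cells = sum(
        len(p_grid[tau] if isinstance(p_grid, dict) else p_grid) for tau in tau_grid
    )
    cell_seeds = iter(child_seeds(seed, n_cells))
    for tau in tau_grid:
        ps = p_grid[tau] if isinstance(p_grid, dict) else p_grid
        for p in ps:
            frac, se = phase_variable(
                p, tau, n_realizations, int(next(cell_seeds)),
                max_time=max_time, max_removed=max_removed,
            )
            rows.append(
                {"tau": tau, "p": p, "n": n_realizations, "phase": frac, "stderr": se}
            )
    return PhaseDiagram(table=pd.DataFrame(rows), max_removed=max_removed)


@dataclass
class BoundaryFit:
    """Phase boundary locations and their power-law summary.

    ``boundary`` has one row per tau: the p where the logistic
    interpolation of the die-out fraction (in ln p) crosses 0.5, with its
    fit uncertainty; taus whose data do not bracket 0.5 are flagged.
    ``prefactor``/``exponent`` describe the least-squares line
    ``ln p_b = ln a + b ln tau``.
    """

    boundary: pd.DataFrame  # columns: tau, p_boundary, p_err, ok
    prefactor: float
    exponent: float
    prefactor_err: float
    exponent_err: float


def _logistic_boundary(ps, phases, errs, n) -> tuple[float, float, bool]:
    """Fit phase(p) to a logistic in ln p; return (p at 0.5, err, ok)."""
    ps = np.asarray(ps, float)
    phases = np.asarray(phases, float)
    if phases.min() > 0.5 or phases.max() < 0.5:
        return math.nan, math.nan, False
    lo = np.log(ps)
    # binomial errors floored so exact 0/1 cells still carry weight
    sigma = np.maximum(np.asarray(errs, float), 0.5 / n)

    def model(lnp, mu, s):
        z = np.clip((lnp - mu) / s, -700.0, 700.0)
        return 1.0 / (1.0 + np.exp(z))

    mu0 = lo[np.argmin(np.abs(phases - 0.5))]
    try:
        popt, pcov = curve_fit(
            model, lo, phases, p0=(mu0, 0.15), sigma=sigma, absolute_sigma=True,
            bounds=([lo.min() - 2.0, 1e-3], [lo.max() + 2.0, 10.0]),
            maxfev=10_000,
        )
        p_b = math.exp(popt[0])
        p_err = p_b * math.sqrt(max(pcov[0, 0], 0.0))
        if np.isfinite(p_b):
            return p_b, p_err, True
    except RuntimeError:
        pass
    # fall back for step-like data the logistic cannot resolve: linear
    # interpolation of the 0.5 crossing in ln p, error = half the spacing
    order = np.argsort(lo)
    lo, phases = lo[order], phases[order]
    for i in range(len(lo) - 1):
        a, b = phases[i], phases[i + 1]
        if (a - 0.5) * (b - 0.5) <= 0 and a != b:
            mu = lo[i] + (a - 0.5) / (a - b) * (lo[i + 1] - lo[i])
            p_b = math.exp(mu)
            return p_b, p_b * (lo[i + 1] - lo[i]) / 2.0, True
    return math.nan, math.nan, False


def phase_boundary(diagram: PhaseDiagram) -> BoundaryFit:
    """Extract the 0.5 phase boundary per tau and fit ``p_b = a tau**b``.

    Per tau the die-out fraction is interpolated by a logistic in ln p
    (monotone, bounded in [0, 1]); the boundary line is a weighted
    least-squares fit in log-log space.  Requires at least 3 p values per
    tau and at least 2 usable boundary points.
    """
    rows = []
    for tau in sorted(diagram.table["tau"].unique()):
        sub = diagram.rows_for_tau(tau)
        if len(sub) < 3:
            rows.append({"tau": tau, "p_boundary": math.nan, "p_err": math.nan, "ok": False})
            continue
        p_b, p_err, ok = _logistic_boundary(
            sub["p"], sub["phase"], sub["stderr"], sub["n"].iloc[0]
        )
        rows.append({"tau": tau, "p_boundary": p_b, "p_err": p_err, "ok": ok})
    boundary = pd.DataFrame(rows)
    good = boundary[boundary["ok"]]
    if len(good) < 2:
        raise ValueError("fewer than 2 usable boundary points; cannot fit power law")

    x = np.log(good["tau"].to_numpy(float))
    y = np.log(good["p_boundary"].to_numpy(float))
    sigma = good["p_err"].to_numpy(float) / good["p_boundary"].to_numpy(float)
    if not np.all(np.isfinite(sigma)) or np.any(sigma <= 0):
        sigma = np.ones_like(y)
    w = 1.0 / sigma**2
    # weighted straight line y = b0 + b1 x with parameter covariance
    A = np.vstack([np.ones_like(x), x]).T
    cov = np.linalg.inv(A.T @ (A * w[:, None]))
    beta = cov @ (A.T @ (w * y))
    return BoundaryFit(
        boundary=boundary,
        prefactor=float(math.exp(beta[0])),
        exponent=float(beta[1]),
        prefactor_err=float(math.exp(beta[0]) * math.sqrt(cov[0, 0])),
        exponent_err=float(math.sqrt(cov[1, 1])),
    )


# ------------------------------------------------------------- geometry


def radius_of_gyration(sites) -> tuple[float, tuple[float, float]]:
    """Radius of gyration and center of mass of a set of cells.

    ``Rg**2`` is the mean squared distance to the center of mass.
    """
    pts = np.asarray(list(sites) if not isinstance(sites, np.ndarray) else sites, float)
    if pts.size == 0:
        raise ValueError("radius_of_gyration of an empty site set")
    pts = pts.reshape(-1, 2)
    cm = pts.mean(axis=0)
    rg2 = ((pts - cm) ** 2).sum(axis=1).mean()
    return float(math.sqrt(rg2)), (float(cm[0]), float(cm[1]))


def spatial_autocorrelation(
    sites,
    max_radius: float,
    bin_width: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged autocorrelation of a removed-site indicator field.

    ``C(offset)`` counts ordered site pairs separated by the offset (FFT
    cross-correlation of the indicator over its bounding box); within each
    radial bin the values ``C/C(0)`` are averaged over the offsets
    enumerated in the bounding-box range.  ``rho`` at the zero bin is 1 by
    construction and the normalization is window-independent.

    Returns ``(bin_centers, rho)`` for bins of ``bin_width`` covering
    [0, max_radius].
    """
    pts = np.asarray(list(sites) if not isinstance(sites, np.ndarray) else sites, int)
    if pts.size == 0:
        raise ValueError("autocorrelation of an empty site set")
    pts = pts.reshape(-1, 2)
    mn = pts.min(axis=0)
    grid = np.zeros(pts.max(axis=0) - mn + 1, dtype=float)
    grid[pts[:, 0] - mn[0], pts[:, 1] - mn[1]] = 1.0
    corr = fftconvolve(grid, grid[::-1, ::-1])
    corr = np.rint(corr)  # exact integer pair counts
    n_sites = float(len(pts))

    nx, ny = grid.shape
    ox = np.arange(-(nx - 1), nx)[:, None]
    oy = np.arange(-(ny - 1), ny)[None, :]
    dist = np.sqrt(ox**2 + oy**2)
    n_bins = int(math.floor(max_radius / bin_width)) + 1
    idx = np.floor(dist / bin_width).astype(int)
    keep = idx < n_bins
    sums = np.bincount(idx[keep], weights=corr[keep], minlength=n_bins)
    counts = np.bincount(idx[keep], minlength=n_bins)
    rho = np.divide(sums, counts * n_sites, out=np.zeros(n_bins), where=counts > 0)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    centers[0] = 0.0
    return centers, rho


_NEIGHBORS_4 = ((1, 0), (-1, 0), (0, 1), (0, -1))
_NEIGHBORS_8 = _NEIGHBORS_4 + ((1, 1), (1, -1), (-1, 1), (-1, -1))


def surface_sites(
    state: LatticeState,
    start: tuple[int, int] = (0, 0),
    connectivity: int = 4,
) -> int:
    """Number of surface sites of the origin-connected removed cluster.

    Flood-fills the cluster of removed sites containing ``start`` and
    counts members with at least one susceptible (non-removed) nearest
    neighbor.  Detached removed islands are excluded.  ``connectivity``
    selects the cluster adjacency (4 is the nearest-neighbor rule; the
    neighbor check in the surface condition always uses the 4
    nearest neighbors).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    removed = {c for c, s in state.site_status.items() if s == simulator.REMOVED}
    if start not in removed:
        raise ValueError("start site is not removed; no cluster to grow from")
    hood = _NEIGHBORS_4 if connectivity == 4 else _NEIGHBORS_8
    seen = {start}
    queue = deque([start])
    surface = 0
    while queue:
        x, y = queue.popleft()
        if any((x + dx, y + dy) not in removed for dx, dy in _NEIGHBORS_4):
            surface += 1
        for dx, dy in hood:
            nxt = (x + dx, y + dy)
            if nxt in removed and nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    return surface


# -------------------------------------------------------------- scaling


@dataclass
class ScalingFit:
    """Result of a power-law growth fit ``count ~ Rg**exponent``."""

    exponent: float
    stderr: float
    chi2: float
    dof: int
    n_points: int
    min_rg: float
    mode: str  # "joint" | "per_p"
    per_p: dict = field(default_factory=dict)

    @property
    def chi2_per_dof(self) -> float:
        return self.chi2 / self.dof if self.dof > 0 else math.nan


def _curve_points(traces, which: str, n_snapshots: int = 16):
    """Snapshot-averaged (log Rg, log count, sigma) across a run bundle.

    Times are log-spaced (per-step points are serially correlated, so using
    all of them would only multiply the point count, not the information);
    the per-point sigma is the run-to-run spread of log count, not the
    standard error of the mean.
    """
    if which not in ("removed", "active"):
        raise ValueError("which must be 'removed' or 'active'")
    t_max = min(len(tr.time) for tr in traces) - 1
    times = np.unique(np.geomspace(1, t_max, n_snapshots).astype(int))
    log_rg, log_ct, err = [], [], []
    for t in times:
        rgs, cts = [], []
        for tr in traces:
            count = tr.removed[t] if which == "removed" else tr.active[t]
            rg = tr.rg_removed[t] if which == "removed" else tr.rg_active[t]
            if count > 0 and rg > 0:
                rgs.append(math.log(rg))
                cts.append(math.log(float(count)))
        if len(rgs) < max(2, len(traces) // 2):
            continue
        cts = np.asarray(cts)
        log_rg.append(float(np.mean(rgs)))
        log_ct.append(float(cts.mean()))
        err.append(float(cts.std(ddof=1)))
    return np.asarray(log_rg), np.asarray(log_ct), np.asarray(err)


def _weighted_line(x, y, sigma):
    sigma = np.where(sigma > 0, sigma, np.nanmax(sigma[sigma > 0]) if np.any(sigma > 0) else 1.0)
    w = 1.0 / sigma**2
    A = np.vstack([np.ones_like(x), x]).T
    cov = np.linalg.inv(A.T @ (A * w[:, None]))
    beta = cov @ (A.T @ (w * y))
    resid = y - A @ beta
    chi2 = float(np.sum(w * resid**2))
    return float(beta[1]), float(math.sqrt(cov[1, 1])), chi2


def growth_scaling_fit(
    traces_by_p: dict,
    which: str = "removed",
    min_rg: float = 20.0,
    mode: str | None = None,
) -> ScalingFit:
    """Fit the growth law ``count ~ Rg**exponent`` from trace bundles.

    ``traces_by_p`` maps an infection probability to its surviving
    realizations.  Two protocols:

    * ``joint`` (default for the removed set): all (p, t) points with
      ``Rg >= min_rg`` enter one weighted log-log line fit — the removed
      set's curves collapse across p;
    * ``per_p`` (default for the active set): one fit per p, exponents
      averaged — the active set's curves do not collapse, only their
      slopes are compared.

    Per-point errors come from the run-to-run spread of log(count) at fixed
    time.  Refuses to fit fewer than 3 points.
    """
    if mode is None:
        mode = "joint" if which == "removed" else "per_p"
    if mode not in ("joint", "per_p"):
        raise ValueError("mode must be 'joint' or 'per_p'")

    curves = {}
    for p, traces in traces_by_p.items():
        if not traces:
            continue
        x, y, e = _curve_points(traces, which)
        keep = x >= math.log(min_rg)
        if keep.sum() > 0:
            curves[p] = (x[keep], y[keep], e[keep])

    if mode == "joint":
        if not curves:
            raise ValueError("no points with Rg >= min_rg to fit")
        x = np.concatenate([c[0] for c in curves.values()])
        y = np.concatenate([c[1] for c in curves.values()])
        e = np.concatenate([c[2] for c in curves.values()])
        if len(x) < 3:
            raise ValueError(f"only {len(x)} points in fit range; need >= 3")
        slope, err, chi2 = _weighted_line(x, y, e)
        return ScalingFit(
            exponent=slope, stderr=err, chi2=chi2, dof=len(x) - 2,
            n_points=len(x), min_rg=min_rg, mode=mode,
        )

    per_p = {}
    for p, (x, y, e) in curves.items():
        if len(x) < 3:
            continue
        slope, err, chi2 = _weighted_line(x, y, e)
        per_p[p] = {"exponent": slope, "stderr": err, "chi2": chi2, "dof": len(x) - 2}
    if not per_p:
        raise ValueError("no p had >= 3 points in the fit range")
    slopes = np.array([v["exponent"] for v in per_p.values()])
    errs = np.array([v["stderr"] for v in per_p.values()])
    k = len(slopes)
    spread = slopes.std(ddof=1) / math.sqrt(k) if k > 1 else 0.0
    stderr = math.sqrt(float(np.mean(errs**2)) / k + spread**2)
    return ScalingFit(
        exponent=float(slopes.mean()),
        stderr=float(stderr),
        chi2=float(sum(v["chi2"] for v in per_p.values())),
        dof=int(sum(v["dof"] for v in per_p.values())),
        n_points=int(sum(v["dof"] + 2 for v in per_p.values())),
        min_rg=min_rg,
        mode=mode,
        per_p=per_p,
    )


def collect_surviving_traces(
    p: float,
    tau: int,
    n_surviving: int,
    t_max: int,
    seed: int,
    max_attempts: int | None = None,
) -> list[EpidemicTrace]:
    """Run full dynamics until ``n_surviving`` realizations reach ``t_max``.

    A realization survives if walkers are still active at ``t_max`` (no
    removed-count cap is applied here).  Raises if ``max_attempts``
    (default ``20 * n_surviving``) is exhausted first.
    """
    cfg = SimConfig.uniform(p, tau, max_time=t_max, max_removed=2**31 - 1)
    if max_attempts is None:
        max_attempts = 20 * n_surviving
    seeds = child_seeds(seed, max_attempts)
    out: list[EpidemicTrace] = []
    for s in seeds:
        tr = simulator.run(cfg, seed=int(s), keep_state=False)
        if not tr.died_out:
            out.append(tr)
            if len(out) == n_surviving:
                return out
    raise RuntimeError(
        f"only {len(out)}/{n_surviving} surviving runs in {max_attempts} attempts "
        f"(p={p}, tau={tau})"
    )


# -------------------------------------------------------------- tables


def r0_table(
    p_list,
    tau_list,
    n_realizations: int,
    seed: int,
) -> pd.DataFrame:
    """Index-case R0 over a (p, tau) grid, flagging the spreading regime.

    Columns: tau, p, r0, stderr, spreading — spreading means the measured
    R0 exceeds the 50%-survival critical value ``2 ln 2``.
    """
    r0_star = theory.critical_r0(0.5)
    cell_seeds = iter(child_seeds(seed, len(p_list) * len(tau_list)))
    rows = []
    for tau in tau_list:
        for p in p_list:
            r0, se = simulator.measure_r0_index_case(
                p, tau, n_realizations, int(next(cell_seeds))
            )
            rows.append(
                {
                    "tau": tau,
                    "p": p,
                    "r0": r0,
                    "stderr": se,
                    "spreading": bool(r0 > r0_star),
                }
            )
    return pd.DataFrame(rows)
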