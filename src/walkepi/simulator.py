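"""Stochastic lattice epidemic driven by heavy-tailed random walkers.

Sites of an unbounded 2D square lattice are susceptible until visited by an
infective walker, which infects a landed-on site with probability ``p``
(possibly region-dependent).  An infected site immediately becomes
*removed* (it can never be infected again) and spawns a brand-new walker
that lives for exactly ``tau`` jumps of its own.  The outbreak starts from
a single index case at the origin, whose site is removed from the start.

Update schedule: synchronous sweeps.  All walkers alive at the start of a
step jump once, in a freshly shuffled roster order; walkers spawned during
the step take their first jump in the next step.  At most one infection can
happen per site (removal is immediate), and a walker landing on a removed
site does nothing.  Sites that were visited but never infected are tracked
separately (``visited-susceptible``) purely for visualization — they remain
fully susceptible.

Two equivalent engines are provided: an inspectable pure-Python
``init_outbreak``/``step`` state machine, and the compiled ``run`` loop
(module :mod:`walkepi._fast`) used for all bulk measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from . import _fast, kernel

__all__ = [
    "UNTOUCHED",
    "VISITED",
    "REMOVED",
    "ACTIVE",
    "UniformField",
    "TwoRegionField",
    "SimConfig",
    "Walker",
    "LatticeState",
    "EpidemicTrace",
    "init_outbreak",
    "step",
    "run",
    "run_two_region",
    "measure_r0_index_case",
    "measure_r0_index_case_two_region",
    "export_snapshot",
]

# raster / site status codes
UNTOUCHED = 0  # never visited, susceptible
VISITED = 1  # visited but not infected, still susceptible
REMOVED = 2  # infected at some point, immune
ACTIVE = 3  # removed site whose spawned walker is still alive (raster only)

_SEED_MASK = 0x7FFFFFFF  # numba reseeding wants a 31-bit value


@dataclass(frozen=True)
class UniformField:
    """Spatially uniform infection probability."""

    p: float

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")

    def probability_at(self, cell) -> float:
        return self.p


@dataclass(frozen=True)
class TwoRegionField:
    """Two half-planes with distinct infection probabilities.

    Region 1 is ``y <= boundary_y`` (probability ``p1``), region 2 is
    ``y > boundary_y`` (``p2``).  The index case starts at signed distance
    ``start_distance`` from the boundary inside region 1, i.e. at cell
    ``(0, boundary_y - start_distance)``.  Walkers cross the border freely.
    """

    p1: float
    p2: float
    boundary_y: int = 0
    start_distance: int = 0

    def __post_init__(self):
        for name in ("p1", "p2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.start_distance < 0:
            raise ValueError("start_distance must be >= 0 (index case in region 1)")

    def probability_at(self, cell) -> float:
        return self.p2 if cell[1] > self.boundary_y else self.p1

    @property
    def start_cell(self) -> tuple[int, int]:
        return (0, self.boundary_y - self.start_distance)


InfectionField = Union[UniformField, TwoRegionField]


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters of one epidemic experiment.

    ``max_time`` and ``max_removed`` are censoring caps: a realization still
    holding active walkers when either cap is hit is classified as
    spreading (``censored_active``).  Defaults follow the convention
    ``max_time = max(100, 20 tau)`` and ``max_removed = 25000``.
    """

    tau: int
    infection_field: InfectionField
    max_time: int | None = None
    max_removed: int = 25_000
    seed: int | None = None

    def __post_init__(self):
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if self.max_time is not None and self.max_time < 1:
            raise ValueError("max_time must be positive")
        if self.max_removed < 1:
            raise ValueError("max_removed must be positive")

    @classmethod
    def uniform(cls, p: float, tau: int, **kw) -> "SimConfig":
        return cls(tau=tau, infection_field=UniformField(p), **kw)

    @classmethod
    def two_region(
        cls,
        p1: float,
        p2: float,
        tau: int,
        boundary_y: int = 0,
        start_distance: int = 0,
        **kw,
    ) -> "SimConfig":
        return cls(
            tau=tau,
            infection_field=TwoRegionField(p1, p2, boundary_y, start_distance),
            **kw,
        )

    @property
    def resolved_max_time(self) -> int:
        if self.max_time is not None:
            return self.max_time
        return max(100, 20 * self.tau)

    @property
    def start_cell(self) -> tuple[int, int]:
        if isinstance(self.infection_field, TwoRegionField):
            return self.infection_field.start_cell
        return (0, 0)


@dataclass
class Walker:
    """An infective agent: current cell, birth cell and jumps left."""

    cell: tuple[int, int]
    birth_cell: tuple[int, int]
    steps_remaining: int


@dataclass
class LatticeState:
    """Sparse epidemic state: touched sites, live walkers, counters."""

    site_status: dict
    walkers: list
    time: int = 0
    cumulative_infections: int = 0

    @property
    def removed_count(self) -> int:
        return sum(1 for s in self.site_status.values() if s == REMOVED)

    @property
    def active_count(self) -> int:
        return len(self.walkers)


@dataclass
class EpidemicTrace:
    """Per-step time series of one realization plus its outcome.

    Arrays are indexed by time (length ``time[-1] + 1``).  ``rg_removed`` is
    the radius of gyration of all removed sites, ``rg_active`` that of the
    birth sites of currently live walkers.  ``removed_region1/2`` split the
    removed count across the two half-planes (region 2 is empty for a
    uniform field).
    """

    time: np.ndarray
    active: np.ndarray
    removed: np.ndarray
    rg_removed: np.ndarray
    rg_active: np.ndarray
    removed_region1: np.ndarray
    removed_region2: np.ndarray
    outcome: str  # "died_out" | "censored_active"
    final_state: LatticeState | None = None
    config: SimConfig | None = None
    seed: int | None = None

    @property
    def died_out(self) -> bool:
        return self.outcome == "died_out"

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.time,
                "active": self.active,
                "removed": self.removed,
                "rg_removed": self.rg_removed,
                "rg_active": self.rg_active,
                "removed_region1": self.removed_region1,
                "removed_region2": self.removed_region2,
            }
        )


def _field_params(config: SimConfig) -> tuple[float, float, bool, int, int]:
    """(p1, p2, two_region, boundary_y, start_y) for the compiled core."""
    f = config.infection_field
    if isinstance(f, TwoRegionField):
        return f.p1, f.p2, True, f.boundary_y, f.boundary_y - f.start_distance
    return f.p, f.p, False, 2**40, 0  # boundary far above: everything region 1


def init_outbreak(config: SimConfig) -> LatticeState:
    """Fresh outbreak state: one walker at the start cell, site removed."""
    if not isinstance(config, SimConfig):
        raise TypeError("config must be a SimConfig")
    start = config.start_cell
    return LatticeState(
        site_status={start: REMOVED},
        walkers=[Walker(cell=start, birth_cell=start, steps_remaining=config.tau)],
        time=0,
        cumulative_infections=0,
    )


def step(state: LatticeState, config: SimConfig, rng: np.random.Generator) -> LatticeState:
    """Advance the epidemic by one synchronous sweep (in place).

    Raises if no walker is active (the dynamics is over).
    """
    if not state.walkers:
        raise RuntimeError("cannot step a state with no active walkers")
    field_ = config.infection_field
    n0 = len(state.walkers)
    order = rng.permutation(n0)
    for i in order:
        w = state.walkers[i]
        w.cell = kernel.sample_jump(w.cell, rng)
        status = state.site_status.get(w.cell, UNTOUCHED)
        if status != REMOVED:
            if rng.random() < field_.probability_at(w.cell):
                state.site_status[w.cell] = REMOVED
                state.cumulative_infections += 1
                state.walkers.append(
                    Walker(cell=w.cell, birth_cell=w.cell, steps_remaining=config.tau)
                )
            elif status == UNTOUCHED:
                state.site_status[w.cell] = VISITED
        w.steps_remaining -= 1
    state.walkers = [w for w in state.walkers if w.steps_remaining > 0]
    state.time += 1
    return state


def run(
    config: SimConfig,
    seed: int | None = None,
    keep_state: bool = True,
) -> EpidemicTrace:
    """Run one realization to extinction or censoring (compiled core).

    ``seed`` overrides ``config.seed``; identical (config, seed) pairs give
    identical traces.  Set ``keep_state=False`` to skip materializing the
    final lattice (cheaper in bulk experiments).
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required (config.seed or the seed argument)")
    seed = int(seed) & _SEED_MASK
    p1, p2, two_region, boundary_y, start_y = _field_params(config)
    (
        active,
        removed,
        rg,
        rg_active,
        r1,
        r2,
        outcome_code,
        site_keys,
        site_status,
        wx,
        wy,
        wbx,
        wby,
        wleft,
    ) = _fast.run_epidemic(
        seed,
        config.tau,
        p1,
        p2,
        two_region,
        boundary_y,
        start_y,
        config.resolved_max_time,
        config.max_removed,
    )
    final_state = None
    if keep_state:
        xs, ys = _fast._unpack_keys(site_keys)
        status_map = {
            (int(x), int(y)): int(s) for x, y, s in zip(xs, ys, site_status)
        }
        walkers = [
            Walker(
                cell=(int(cx), int(cy)),
                birth_cell=(int(bx), int(by)),
                steps_remaining=int(sl),
            )
            for cx, cy, bx, by, sl in zip(wx, wy, wbx, wby, wleft)
        ]
        final_state = LatticeState(
            site_status=status_map,
            walkers=walkers,
            time=len(active) - 1,
            cumulative_infections=int(removed[-1]) - 1,
        )
    return EpidemicTrace(
        time=np.arange(len(active)),
        active=active,
        removed=removed,
        rg_removed=rg,
        rg_active=rg_active,
        removed_region1=r1,
        removed_region2=r2,
        outcome="died_out" if outcome_code == _fast.DIED_OUT else "censored_active",
        final_state=final_state,
        config=config,
        seed=seed,
    )


def run_two_region(config: SimConfig, seed: int | None = None, **kw) -> EpidemicTrace:
    """Run a two-region scenario; the trace carries per-region counts."""
    if not isinstance(config.infection_field, TwoRegionField):
        raise ValueError("run_two_region requires a TwoRegionField config")
    return run(config, seed=seed, **kw)


def child_seeds(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit streams from one master seed."""
    return (
        np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) & _SEED_MASK
    ).astype(np.int64)


def measure_r0_index_case(
    p: float,
    tau: int,
    n_realizations: int,
    seed: int,
) -> tuple[float, float]:
    """Mean secondary infections by the index case alone, with std. error.

    Only the index walker is simulated for its ``tau`` jumps; sites it
    infects are removed *for it*, so revisits cannot re-infect, but no
    secondary walkers are stepped.  This is the quantity the corrected-R0
    theory describes (self-intersections of a single path).
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    counts, _ = _fast.index_case_counts(
        int(seed) & _SEED_MASK, int(tau), float(p), float(p), False, 2**40, 0, int(n_realizations)
    )
    mean = float(counts.mean())
    se = float(counts.std(ddof=1) / np.sqrt(n_realizations)) if n_realizations > 1 else float("nan")
    return mean, se


def measure_r0_index_case_two_region(
    p1: float,
    p2: float,
    tau: int,
    n_realizations: int,
    seed: int,
    boundary_y: int = 0,
    start_distance: int = 0,
) -> dict:
    """Per-region index-case infection counts for a two-half-plane field."""
    field_ = TwoRegionField(p1, p2, boundary_y, start_distance)
    c1, c2 = _fast.index_case_counts(
        int(seed) & _SEED_MASK,
        int(tau),
        p1,
        p2,
        True,
        boundary_y,
        boundary_y - start_distance,
        int(n_realizations),
    )
    n = n_realizations
    return {
        "r0_region1": float(c1.mean()),
        "r0_region1_stderr": float(c1.std(ddof=1) / np.sqrt(n)),
        "r0_region2": float(c2.mean()),
        "r0_region2_stderr": float(c2.std(ddof=1) / np.sqrt(n)),
    }


def export_snapshot(state: LatticeState, window) -> np.ndarray:
    """Raster of status codes over an inclusive window.

    ``window = ((xmin, xmax), (ymin, ymax))``; returns an array of shape
    ``(ymax-ymin+1, xmax-xmin+1)`` with row index = y offset.  Codes:
    0 untouched susceptible, 1 visited-susceptible, 2 removed, 3 removed
    site whose spawned walker is still active.
    """
    (xmin, xmax), (ymin, ymax) = window
    if xmax < xmin or ymax < ymin:
        raise ValueError("empty snapshot window")
    grid = np.zeros((ymax - ymin + 1, xmax - xmin + 1), dtype=np.int8)
    for (x, y), s in state.site_status.items():
        if xmin <= x <= xmax and ymin <= y <= ymax:
            grid[y - ymin, x - xmin] = s
    for w in state.walkers:
        bx, by = w.birth_cell
        if xmin <= bx <= xmax and ymin <= by <= ymax:
            grid[by - ymin, bx - xmin] = ACTIVE
    return grid
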