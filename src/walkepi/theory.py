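"""Closed-form predictions for the random-walk epidemic.

Core results implemented here:

* the corrected basic reproduction number

      R0(p, tau) = p tau / (1 + K p ln(tau / tau0)),

  where ``K = 1/(4 pi c)`` and ``tau0 ~ 1/c`` come from the small-q
  curvature ``c`` of the jump kernel's structure factor.  The correction
  accounts for the recurrence of 2D random walks: a self-intersecting path
  wastes landings on already-removed sites, so R0 grows slower than the
  mean-field (panmictic) estimate ``p tau``;

* the branching-process extinction probability ``P0`` solving
  ``P0 = exp(-R0 (1 - P0))`` under Poisson offspring, which places the
  phase boundary at ``R0 = 2 ln 2 ~ 1.39`` (the iso-R0 line where half the
  outbreaks survive) rather than at ``R0 = 1``;

* the two-half-plane generalization (regions with probabilities p1/p2
  separated by a straight border at distance d from the index case);

* directed-percolation exponent algebra for the critical scaling of the
  active set, ``d_cap = d - beta / nu_perp``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import bisect
from scipy.special import erf

from .kernel import KernelSummary

__all__ = [
    "DP_EXPONENTS_2D",
    "DPExponents",
    "BranchingOutcome",
    "r0_naive",
    "r0_predicted",
    "critical_p",
    "extinction_probability",
    "critical_r0",
    "localization_probability_n_cases",
    "two_region_r0",
    "two_region_ratio",
    "dp_intersection_dimension",
]


def _log_term(tau: float, constants: KernelSummary) -> float:
    return float(np.log(tau / constants.tau0))


def r0_naive(p: float, tau: float) -> float:
    """Mean-field estimate ``R0 = p tau`` (every landing a fresh site)."""
    return p * tau


def r0_predicted(p: float, tau: float, constants: KernelSummary) -> float:
    """Recurrence-corrected basic reproduction number.

    ``R0 = p tau / (1 + K p ln(tau/tau0))``.  Reduces to ``p tau`` for
    ``p -> 0`` and at ``tau = tau0``; the derivation is asymptotic in tau,
    so accuracy degrades for ``tau`` of order ``tau0``.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    return p * tau / (1.0 + constants.K * p * _log_term(tau, constants))


def critical_p(tau: float, constants: KernelSummary, r0_star: float | None = None) -> float:
    """Infection probability at which R0 reaches the critical value.

    Inverts the corrected R0 formula at ``r0_star`` (default ``2 ln 2``,
    the 50%-survival boundary):
    ``p_c = R* / (tau - R* K ln(tau/tau0))``.
    """
    if r0_star is None:
        r0_star = critical_r0(0.5)
    denom = tau - r0_star * constants.K * _log_term(tau, constants)
    if denom <= 0:
        raise ValueError("tau too small: no subcritical p exists at this R0")
    return r0_star / denom


def extinction_probability(r0: float, tol: float = 1e-12) -> float:
    """Probability that an outbreak with Poisson(R0) offspring dies out.

    The unique fixed point of ``P0 = exp(-R0 (1 - P0))`` in (0, 1) for
    ``R0 > 1``; exactly 1 for ``R0 <= 1`` (subcritical or critical
    branching always goes extinct).  Bracketed bisection to ``tol``.
    """
    if r0 < 0:
        raise ValueError(f"R0 must be nonnegative, got {r0}")
    if r0 <= 1.0:
        return 1.0

    # Work in the survival probability q = 1 - P0: the fixed point becomes
    # q = 1 - exp(-R0 q), whose interior root is well separated from the
    # trivial root q = 0 (g'(0) = R0 - 1 > 0) and, via expm1, numerically
    # stable even as R0 -> 1+ where P0 -> 1.
    def g(q: float) -> float:
        return -np.expm1(-r0 * q) - q

    q_root = bisect(g, 1e-12, 1.0, xtol=tol)
    return float(1.0 - q_root)


def critical_r0(surviving_fraction: float) -> float:
    """R0 at which a given fraction of single-seed outbreaks survives.

    Closed form from the fixed-point equation with ``P0 = 1 - f``:
    ``R0 = -ln(P0) / (1 - P0)``; at f = 0.5 this is ``2 ln 2 ~ 1.386``.
    """
    if not 0.0 < surviving_fraction < 1.0:
        raise ValueError("surviving_fraction must be in (0, 1)")
    p0 = 1.0 - surviving_fraction
    return float(-np.log(p0) / (1.0 - p0))


def localization_probability_n_cases(r0: float, n_cases: int) -> float:
    """Probability that an epidemic seeded by N index cases dies out.

    First-order approximation ``P0(R0)**N`` (independent index cases in
    identical environments).
    """
    if n_cases < 1:
        raise ValueError("n_cases must be a positive integer")
    return extinction_probability(r0) ** n_cases


@dataclass(frozen=True)
class BranchingOutcome:
    """Branching-process summary for one (R0, N) scenario.

    ``p1`` is the extinction probability of a secondary outbreak; the
    theory stipulates the secondary environment matches the index case's,
    so ``p1 = p0`` unless overridden.
    """

    r0: float
    p0: float
    n_cases: int = 1
    p1: float | None = None

    def __post_init__(self):
        if self.p1 is None:
            object.__setattr__(self, "p1", self.p0)
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must be a probability")
        if self.r0 <= 1.0 and self.p0 != 1.0:
            raise ValueError("subcritical branching must have p0 = 1")

    @property
    def p_localized(self) -> float:
        return self.p0**self.n_cases

    @classmethod
    def from_r0(cls, r0: float, n_cases: int = 1) -> "BranchingOutcome":
        return cls(r0=r0, p0=extinction_probability(r0), n_cases=n_cases)


def two_region_r0(
    p1: float,
    p2: float,
    d: float,
    tau: float,
    constants: KernelSummary,
) -> tuple[float, float]:
    """Expected index-case infections in each of two half-plane regions.

    The walker starts at distance ``d >= 0`` from the straight border,
    inside region 1; diffusive spreading splits its time between regions
    via an error function:

        R0_i = p_i tau / (2 (1 + K p_i ln(tau/tau0))) * [1 ± erf(d / (2 sqrt(c tau)))]

    (+ for region 1, - for region 2).  At ``p1 = p2`` the two terms sum to
    the single-region R0 for every d.
    """
    if d < 0:
        raise ValueError("d must be nonnegative (index case inside region 1)")
    if tau <= 0:
        raise ValueError("tau must be positive")
    e = float(erf(d / (2.0 * np.sqrt(constants.c * tau))))
    lt = _log_term(tau, constants)
    r1 = p1 * tau / (2.0 * (1.0 + constants.K * p1 * lt)) * (1.0 + e)
    r2 = p2 * tau / (2.0 * (1.0 + constants.K * p2 * lt)) * (1.0 - e)
    return r1, r2


def two_region_ratio(
    p1: float,
    p2: float,
    tau: float,
    constants: KernelSummary,
) -> float:
    """Ratio R0(region 2) / R0(region 1) for a walker starting on the border.

    ``(p2/p1) (1 + K p1 ln(tau/tau0)) / (1 + K p2 ln(tau/tau0))`` — tends to
    ``p2/p1`` for short walks and to 1 for long walks (a long-lived walker
    revisits its contacts so often that per-meeting infectivity stops
    mattering).
    """
    if p1 <= 0:
        raise ValueError("p1 must be positive")
    lt = _log_term(tau, constants)
    return (p2 / p1) * (1.0 + constants.K * p1 * lt) / (1.0 + constants.K * p2 * lt)


@dataclass(frozen=True)
class DPExponents:
    """Critical exponents of (d+1)-dimensional directed percolation.

    Values with quoted uncertainties from the simulation literature; these
    are inputs to the universality-class prediction, not fitted here.
    """

    beta: float
    nu_perp: float
    nu_parallel: float
    d: int = 2
    beta_err: float = 0.0
    nu_perp_err: float = 0.0
    nu_parallel_err: float = 0.0

    def __post_init__(self):
        if min(self.beta, self.nu_perp, self.nu_parallel) < 0:
            raise ValueError("exponents must be positive")


#: (2+1)-dimensional directed percolation
DP_EXPONENTS_2D = DPExponents(
    beta=0.583,
    nu_perp=0.733,
    nu_parallel=1.295,
    d=2,
    beta_err=0.003,
    nu_perp_err=0.008,
    nu_parallel_err=0.006,
)


def dp_intersection_dimension(
    exponents: DPExponents = DP_EXPONENTS_2D,
) -> tuple[float, float]:
    """Fractal dimension of a fixed-time slice of the critical cluster.

    ``d_cap = d - beta / nu_perp``, with first-order propagation of the
    exponent uncertainties.  For (2+1)D directed percolation this predicts
    that the number of currently infected sites scales with the active
    set's radius of gyration to the power ~1.20; mean field gives 1.
    """
    e = exponents
    d_cap = e.d - e.beta / e.nu_perp
    err = np.sqrt(
        (e.beta_err / e.nu_perp) ** 2 + (e.beta * e.nu_perp_err / e.nu_perp**2) ** 2
    )
    return float(d_cap), float(err)
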