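# Methods

## Model definition

Sites of an unbounded 2D square lattice are susceptible, removed, or
(bookkeeping only) visited-but-susceptible. A single index case sits at the
origin; its site is removed from the start, which is why the measured R₀ at
`p = τ = 1` falls slightly below 1 — a walker that never leaves its own cell
infects nobody. Infective agents are random walkers living on the dual
lattice (cell centers). Each step a walker draws a jump length
`r = (3u)^(−1/3)`, `u ~ U(0,1]`, and a uniform angle, moves, and the landing
point is snapped to its cell, `(⌊x+½+r sinθ⌋, ⌊y+½+r cosθ⌋)` relative to
integer cell indices. The jump-length density is `φ(r) = 1/r⁴` above
`r_min = 3^(−1/3)`; the exact tail is `P(r > R) = 1/(3R³)`, so 2/3 of jumps
are shorter than one lattice constant and 23/24 shorter than two. Drawing
`u` as `1 − U[0,1)` excludes `u = 0` (an infinite jump); the largest length
representable in a 10⁹-jump campaign is ~10⁵ lattice units, far inside the
packed 64-bit cell keys used by the hash-map lattice.

A landing on a non-removed site triggers a Bernoulli(p) infection trial
(`p` of the landing cell's region); success removes the site and spawns a
new walker there; failure only marks it visited — visited sites remain
fully infectable. Landings on removed sites do nothing.

### Update schedule

Sweeps are synchronous. Every walker alive at the start of step `t` jumps
once, in a freshly shuffled roster order (so no site is systematically
claimed by older walkers; at most one infection per site per step happens
automatically because removal is immediate). Walkers spawned during step
`t` jump first at `t+1`, and a walker's lifetime τ counts its *own* jumps:
every agent gets exactly τ landings, matching the τ of the analytical
theory. Alternatives (birth-step activation, fixed ordering) change
nothing at leading order but would make each agent's exposure depend on
its birth phase.

Two engines implement these rules: a readable pure-Python state machine
(`init_outbreak`/`step`) and a numba-compiled loop used for campaigns
(~1.5 M jump events/s on one core, hash-map site storage, ~10⁹ events in
the largest default campaign). The test suite checks the two agree in
deterministic corners and statistically under replication.

### Censoring

A realization ends when no walkers remain (`died_out`) or when a cap is
hit (`censored_active`): `max_time` (default `max(100, 20τ)`) or
`max_removed` (default 25 000). Censored runs count as spreading in the
phase variable. The phase-diagram campaigns use `max_removed = 4000`: on
the same grid and seeds the boundary fit is statistically identical to the
25 000-cap run (prefactor 1.99 ± 0.02 vs 2.00 ± 0.02, exponent −1.066 ±
0.004 vs −1.068 ± 0.004) at a fifth of the cost, because a run still
growing at 4000 removed sites is already supercritical beyond doubt.

## Kernel constants

The recurrence correction needs the small-q curvature `c` of the structure
factor `χ(q) = E[e^{iq·Δ}]` of the *discretized* landed displacement Δ
(the lattice snap adds measurable variance: the continuous jump would give
`E[r²]/4 ≈ 0.36`). It is estimated as `c = (1/2N) Σ x_i²` over the landed
x-components, the q²-coefficient of the cosine expansion. Then
`K = 1/(4πc)` exactly and `τ₀ = 1/c` at leading order (the O(1) constant
`q₀ ≈ 1` under the logarithm is absorbed into τ₀; only `c`, `K`, `τ₀` are
exposed).

A caveat the package reports honestly: `φ ∝ r⁻⁴` has an infinite fourth
moment, so the summands `x²` have infinite variance and the estimator of
`c` converges slowly (stable-law fluctuations ~ n^(−1/3)) with a plug-in
standard error that understates the spread. Numerical quadrature of
`E[⌊½ + r sinθ⌋²]/2` gives the asymptotic value `c = 0.4478`; single
10⁶-sample estimates scatter roughly between 0.44 and 0.47 depending on
whether a few very long jumps land in the batch. Derived quantities are
insensitive: the critical `p` at τ = 50 moves by under 0.5% across that
whole range.

The quasilocality fractions quoted for the kernel (≈66.8% "adjacent",
≈95.7% "within 2") are fractions of the *continuous jump length*
(`P(r ≤ 1) = 2/3`, `P(r ≤ 2) = 23/24`): a jump shorter than one lattice
constant can reach at most the eight surrounding cells. The cell-based
adjacency fraction is much larger (~92.5%, since many jumps with `r`
slightly above 1 still snap to an adjacent cell) and is reported as a
diagnostic alongside.

## R₀: measurement and theory

`measure_r0_index_case` simulates the index walker alone for its τ jumps;
sites it infects are removed *for it* (revisits cannot re-infect), and no
secondary walkers move. This is exactly the quantity the theory describes
— the self-intersection statistics of one path — and it calibrates against
the reference grid values to within quoted errors. The corrected formula
`R₀ = pτ / (1 + K p ln(τ/τ₀))` is evaluated for any τ ≥ 1, but it is an
asymptotic result: at τ ≈ τ₀ ≈ 2.2 it recovers only part of the correction
(e.g. τ = 3, p = 1/4: predicted 0.740, measured 0.695, well-mixed 0.75),
while at τ = 128 it matches simulation to better than 1%.

The extinction fixed point `P₀ = exp(−R₀(1−P₀))` (Poisson offspring,
secondary environments assumed identical to the index case's) is solved in
the survival variable `q = 1 − P₀` with `expm1` and bracketed bisection to
1e−12: the naive bracket on `P₀` collapses numerically for R₀ → 1⁺, where
the interior root approaches the trivial root at 1 within float spacing.
For R₀ ≤ 1 the function returns exactly 1. The 50%-survival critical point
is the closed form `R₀* = −ln P₀/(1−P₀) = 2 ln 2`.

In the two-region half-plane model, region 1 is `y ≤ boundary_y` and the
index case starts `d` rows inside region 1. The erf split of the theory
treats the border as a continuum line; on the lattice the boundary *row*
belongs to region 1, so at `d = 0` the measured split favors region 1 by
an O(1/√(cτ)) margin that fades with τ — the tests check the direction and
decay of this discreteness effect rather than exact symmetry.

## Phase diagram and boundary

The phase variable is the die-out fraction over `n` capped realizations
with a binomial standard error. Per τ, the boundary is the `p` at which a
two-parameter logistic in `ln p` crosses ½ (monotone, bounded — the
interpolating-function choice is otherwise free); cells with exact 0/1
fractions keep a floored error `0.5/n` so they still constrain the fit.
τ-rows whose data do not bracket ½ are flagged and excluded. The boundary
line `ln p_b = ln a + b ln τ` is a weighted least-squares fit with the
boundary-location uncertainties (the unweighted alternative moves the
scaled-down exponent by less than its error). Default campaign:
τ ∈ {4, 8, 16, 32, 64}, nine p per τ geometrically spanning
`p_c(theory)/2 … 2 p_c(theory)`, 200 realizations per cell.

## Cluster geometry and growth scaling

Radius of gyration: root mean squared distance to the center of mass of
the site set. Spatial autocorrelation: FFT pair counts of the removed-site
indicator over its bounding box, `C(offset)/C(0)` averaged over the
offsets of each 1-lattice-unit radial bin (window-independent pair-count
normalization; the averaging domain of the underlying expectation is
otherwise unspecified, and this reading makes ρ(0) = 1 exact). Surface
sites: 4-connected flood fill of the removed cluster from the origin,
counting members with at least one non-removed 4-neighbor (8-connectivity
available as an option).

Growth fits `count ∝ Rg^exponent` use snapshot curves: 16 log-spaced times
per run bundle (per-step points are serially correlated and add no
information), averaging `log count` and `log Rg` across surviving runs at
each snapshot, with the per-point σ taken as the *run-to-run spread* of
`log count` — not the standard error of the mean, which would overstate
the information content of correlated curves. The removed set uses one
joint weighted fit across all p (its curves collapse); the active set is
fitted per p and the exponents averaged (its curves do not collapse). Fit
range defaults to `Rg ≥ 20`.

At the default desk scale (τ = 50, p ∈ {0.04, 0.05, 0.06}, 20 surviving
runs to t = 500) the removed-set exponent comes out ≈ 2.3 ± 0.2 with
χ²/dof ≈ 1: consistent with the asymptotic 2.04(2), but pulled upward by
the fill-in crossover — the local slope falls from ~2.9 at Rg ≈ 20–35 to
~2.0 by Rg ≈ 60–100, and t = 500 runs only reach Rg ≈ 45–80. The
full-scale campaign (`--full`: seven p down to 0.03, 500 runs, t = 1500)
reaches far larger Rg where the joint fit settles onto the asymptotic
value. The active-set exponent (≈1.2, the directed-percolation slice
dimension d∩ = d − β/ν⊥ = 1.20(1) from β = 0.583(3), ν⊥ = 0.733(8)) and
the surface exponent need the full-scale campaign; at desk scale the
fitting machinery is validated by planted-exponent recovery, the 4n−4
perimeter law and brute-force oracles instead.

## Randomness and reproducibility

Every stochastic entry point takes an explicit seed or `numpy` Generator.
Campaigns split a master seed into independent 31-bit child streams via
`SeedSequence`; the compiled core seeds numba's own Mersenne-Twister state
per realization. Identical (config, seed) pairs reproduce traces bit for
bit. The kernel-sampling draw order (all `u`, then all angles) is part of
the reproducibility contract.

## What the desk-scale experiments do and do not show

The scaled-down campaigns reproduce the *structure* of the full results —
the boundary's power law (scaled-down fit `p_b ≈ 2.0 τ^−1.07`), the
iso-R₀ character of the boundary, the compact growth of the removed set —
with honest error bars, but they cannot pin exponents to the second
decimal, and the critical-region observables (active-set scaling, surface
scaling) are out of their reach entirely. The model itself idealizes
aggressively: walkers have no home locations (real commuting localizes
outbreaks further), re-seeding a burned lattice (second waves) is not
simulated, and the lattice is a homogeneous-density stand-in for real
geography.
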