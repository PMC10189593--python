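# Methods

## Model

Soil quality is a birth–death Markov chain on {0, …, K} driven by the crop
choice: a cover-crop season moves state *i* to min(*i* + *a*, K), a
cash-crop season to max(*i* − *b*, 0). Boundary jumps clip, leaving
self-transition mass at 0 and K; this is the simplest bounded reading of
the dynamics and, for *a* = *b* = 1, gives the geometric stationary law
x_i ∝ r^i with r = γ/(1 − γ) by detailed balance — used throughout as the
closed-form oracle for the solver.

Under randomized rotation (cover with probability γ each season,
independently) the chain for 0 < γ < 1 has a unique stationary
distribution, computed from the null space of Tᵀ − I
(`scipy.linalg.null_space`), never by long simulation. At the endpoints
the chain is absorbing and the stationary law is taken as the point mass
actually reached from any start: δ₀ at γ = 0, δ_K at γ = 1. This makes the
monoculture limits exact: P_win(0) = p₁, P_win(1) = p.

### Payoff-timing convention

The per-season payoff is +1 with the crop's profit probability, −1
otherwise. For a cash season the probability is p₁ or p₂ depending on
whether the soil quality is ≤ θ; *which* season's quality is ambiguous in
a chain that moves within the season. Both readings are implemented:

- `timing="pre"`: classify on the quality at the start of the season.
  P_win is then the literal stationary sum q₁·Σ_{i≤θ} x_i + q₂·Σ_{i>θ} x_i
  with q_j = γp + (1−γ)p_j. Reference value at (K=10, a=b=1, θ=2, p=0.4,
  p₁=0, p₂=0.8, γ=0.6): **0.5511**.
- `timing="post"` (default): classify on the end-of-season quality
  max(i − b, 0). Reference value: **0.5448**.

The default matches the convention under which the standard worked example
of this model prints 0.544. The choice changes every derived quantity
(regions, θ\*, scans), so the CLI logs it in every manifest. Monoculture
limits hold exactly under both.

### Winning regions and θ\*

`win_region` scans γ on a uniform grid (default step 0.005, capped at
0.01) and refines each sign change of P_win − ½ by bisection to
`refine_tol` (default 10⁻⁶). Observed curves are unimodal with a single
winning interval; if several disjoint intervals ever appear the widest is
returned with a warning rather than silently truncated. `critical_theta`
evaluates every θ ∈ {0..K} rather than assuming monotonicity in θ (the
monotone pattern is asserted in tests, not presumed in code).

Non-integer depletion ratios (e.g. b = 1.5a) are represented by integer
pairs such as (a, b) = (2, 3); the state grid stays integer.

## Fertilizer

Fertilizer acts only on a rotation already at steady state: a nonnegative
mass profile f is added to x\* and renormalized,
x′_i = (x_i + f_i)/(1 + Σf). The illustrative profile is the skew-normal
density evaluated at integer soil qualities,

    f_i = exp(−(i−μ)²/2σ²) · erfc(−α(i−μ)/√2σ) / (√(2π)σ),

i.e. the standard 2·φ·Φ skew-normal pdf (`scipy.stats.skewnorm`), with
location μ (soil-quality units), spread σ > 0 and skewness α. f is *not*
renormalized before mixing — its total mass is the strength of the
intervention. Functions also accept an explicit profile vector, which is
how the directional claims are tested: mass placed wholly above θ raises
θ\*, mass at the bottom lowers it, the zero profile is neutral.
`fertilizer_decision_report` reports θ\* with/without fertilizer and a
verdict in {beneficial, harmful, neutral}. No canonical (μ, σ, α) values
exist for the published θ\*-shift illustrations, so those specific shifts
are not asserted anywhere — only the direction mechanism is.

## Simulator

Seeded Monte-Carlo with one RNG stream per replicate, spawned from the
master seed via `numpy.random.SeedSequence`; replicate r is bit-identical
whatever `n_reps` is. Per season: draw or read the crop, update soil
(clipped), draw the ±1 payoff with the timing-convention probability.
Capital starts at 0 and accrues from season 1. The win probability is
estimated as P̂ = (1 + s)/2 where s is the OLS slope of mean capital vs
season over *all* seasons — the transient from the initial soil quality
(default q0 = 0, a barren start) is deliberately included; callers can
exclude it via `occupancy_frequencies`' burn-in when comparing with the
stationary law. The standard error of P̂ comes from the spread of
per-replicate slopes. At the reference parameters the seeded estimate at
m = 10 000 × n = 1000 lands at ≈ 0.544 with stderr ≈ 2·10⁻⁴.

The generator emulates exactly the study conditions of the model —
i.i.d. crop draws, state-dependent Bernoulli payoffs, unit yields. It does
not emulate real-world features such as yield magnitudes, price dynamics,
weather correlation across seasons, or spatial heterogeneity; passing
tests validate the stochastic model, not field data.

## Deterministic schedules

A schedule (α₁, …, α_n) repeats with period Σα_i. Its soil trajectory is
deterministic on a finite state space, so it enters a limit cycle; the
exact long-run win probability is the mean per-season win probability over
that cycle, found by detecting the first repeated (position-in-period,
soil) pair. No simulation or truncation error is involved. Zero-net-drift
schedules (a·Σα_odd = b·Σα_even) can have q0-dependent cycles; q0 defaults
to 0 and is recorded in the result rather than hidden. The (α₁, α₂) grid
scan ranks schedules by win probability rounded to two decimals (ranking
time only — computation keeps full precision), breaking ties by shorter
period then lexicographic order so the ranking is total and deterministic.
The Monte-Carlo route through the simulator cross-checks the exact
evaluator in tests.

## Pathogen extension

The pathogen load n walks on {0..L}: up by `growth_step` (default 1) with
probability 1 − γ (a cash season feeds it), down by `decay_step` (default
1) with probability γ, clipped. Severity β ∈ [0, 1] maps the stationary
load law y onto effective profit probabilities; the default mapping leaves
the cover crop untouched and suppresses cash probabilities linearly,
p_i_eff = p_i·(1 − β·E_y[n]/L). This load chain and mapping are this
package's own modelling choices, kept behind a pluggable
`SeverityMapping` hook so alternative derivations drop in. The effective
win probability multiplies marginal soil and load summaries — the
correlation of the crop draw with both states is knowingly ignored, and
`joint_chain_win_probability` (the exact soil × load product chain) is
provided as a diagnostic of how much that matters. β = 0 recovers the
baseline model exactly. `gamma_opt` grid-searches γ (step ≤ 0.005) and
refines with bounded scalar minimization; it is deterministic, and the
refined value is never allowed to fall below the best grid point.

## Numerical choices and problem sizes

- Stationary solver tolerance: null-space rcond 10⁻¹⁰; row-stochasticity
  checked to 10⁻¹².
- Default grids: 0.005 for winning regions and θ\*, 0.002 for γ_opt;
  bisection/refinement tolerances 10⁻⁶–10⁻⁷.
- Test-suite simulation sizes (thousands of replicates × 1–2 thousand
  seasons) are chosen so Monte-Carlo checks resolve 3-standard-error bands
  in seconds; the headline m = 10 000 × n = 1000 run takes ~2 s
  vectorized. Occupancy comparisons discount autocorrelation within a
  trajectory by a conservative effective-sample factor (~50 seasons per
  independent draw).

## Known limitations

- Soil quality is a unitless integer; no economic (price-weighted) yield.
- The pathogen dynamics are a minimal stand-in parameterized for shape
  (monotone suppression, β = 0 identity), not a mechanistic disease model.
- Fertilizer is a steady-state perturbation; transition dynamics are
  untouched, so transient fertilizer effects are out of scope.
- The CLI scan covers (α₁, α₂) pairs; longer schedules are supported by
  the library API but not packaged as an experiment.
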