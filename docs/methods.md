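# Methods

## The structured PDE and its exact solution

Cells are described by a density `p(φ, t)` over the cycle-position
coordinate `φ ∈ [0, 1]`, obeying the conservation law
`∂p/∂t + ∂(v(φ) p)/∂φ = 0` with piecewise-constant velocity (`v` on the G1
half `[0, 1/2]`, `u` on the G2 half `(1/2, 1]`), division boundary
condition `v p(0, t) = 2 u p(1, t)` and uniform initial densities `p0`
(G1) and `q0 = s p0` (G2).  Cell death is not modelled (optimal growth
conditions); the phase boundary is fixed at `φ = 1/2` without loss of
generality since only the durations `L1 = 1/(2v)` and `L2 = 1/(2u)`
matter.  Every cell takes exactly `η1 = L1 + L2` hours per cycle (a
"timer" model: no inter-mitotic-time dispersion), which is the strongest
idealisation in the model — real lineages desynchronise, damping the
oscillations this model sustains forever.

Characteristics advance at speed `v` or `u`, double the carried density at
each division wrap, and rescale it by the velocity ratio at each phase
boundary.  The solution at any time is piecewise constant with at most
four pieces; which of the four branch layouts applies is decided by the
within-cycle time `τ = t − k η1` (`k = ⌊t/η1⌋` completed cycles) relative
to `min(L1, L2)` and `max(L1, L2)` and by the sign of `v − u`.  (A quoted
form of the within-cycle time with a `+ k η1` sign is a typo: periodicity
`π2(t + η1) = π2(t)` and the doubling `p(φ, t + η1) = 2 p(φ, t)` require
the subtraction.)  When `v = u` the two middle layouts have zero width and
the dispatch degenerates cleanly to the early/late branches.  Intervals
are half-open `[a, b)`; values at jump points are right-limits — phase
counts are integrals, so the convention is observable-free.

Integrating the pieces gives closed forms for the phase counts, the total
count `N(t)` (continuous, piecewise linear in `τ` up to the `2^k` factor,
with a single kink at `τ = 1/(2u)`), the G2 proportion `π2(t)` (a ratio of
linear functions of `τ` on each of at most three segments), and the growth
rate `β(t) = N'(t)/N(t)` (right-limit at kinks).  `π2` is independent of
`p0` at fixed `s`.  For large `t` the factor `2^k` overflows doubles after
~1000 cycles, so `log_total_population` computes `ln N = k ln 2 + ln(·)`
directly.

## Cycle averages

Both `β` and `π2` are periodic; their cycle means are

- `β̄ = ln 2 / η1` exactly (the population doubles once per cycle), and
- `π̄2 = (1/η1) ∫ π2 dt`, evaluated segment-by-segment.  Each segment is
  `(a + b τ)/(c + d τ)`, whose antiderivative is `(b/d) τ + (ad − bc)/d² ·
  ln(c + dτ)`.  The two terms cancel catastrophically when `|d·Δτ/(c+dτ0)|`
  is small (extreme `s`), so the implementation switches to the power
  series `Σ (−y)^n (Δ/C)[A/(n+1) + BΔ/(n+2)]`, `y = dΔ/C`, below `|y| = 0.5`;
  the result is accurate to ~1e-15 uniformly in `s` (verified against
  adaptive quadrature to 1e-8 over wide random sweeps, and to ~4e-9 noise
  at `|log10 s| > 6` where naive evaluation produces O(1) garbage).
  A published polynomial-in-`s` closed form for the `v > u` case does not
  agree with quadrature except at `s = 1` (apparent typesetting error in
  one log argument); the per-segment form above is used instead and the
  quadrature routine is kept as an independent oracle.

The within-cycle extrema of `π2` lie at the segment kinks `{0, L1, L2}`
(each segment is monotone), giving the peak-to-peak amplitude `A`
analytically; a dense-grid scan cross-validates this in the tests.  Ties
resolve to the earliest attaining time.  Note the analytic extrema for the
standard example (`v = 1/16`, `u = 1/28`) are max `π2 = 0.8104` at 14 h for
`s = 10^-0.605` (A = 0.6115) and min `0.2738` at 8 h for `s = 10^2.645`
(A = 0.7240); commonly quoted two-decimal amplitudes (0.65, 0.75) derive
from reading trajectory plots and differ from the exact values by ~0.03.
An independent particle-characteristics simulation reproduces the analytic
values.

## The compartment ODE and matching

The linear system `G1' = 2k2 G2 − k1 G1`, `G2' = k1 G1 − k2 G2` is solved
exactly by eigen-decomposition of its rate matrix (an adaptive integrator
is kept as a test oracle only).  The proportion dynamics
`g2' = k1 − (k1+k2) g2 − k2 g2²` settle to
`g̃2 = [−(k1+k2) + √(k1² + 6k1k2 + k2²)]/(2k2)` and the long-term growth
rate is `λ⁺ = k2 g̃2`.

Matching sets `λ⁺ = β̄` and `g̃2 = π̄2`.  The inversion
`(λ⁺, g̃2) → (k1, k2)` uses `k2 = λ⁺/g̃2` and
`k1 = λ⁺(1 + g̃2)/(1 − g̃2)`, the exact solution of the steady-state
balance (round-trip identity with the forward observables to 1e-10).  An
alternative algebraic form `k1 = (g̃2 + 2λ⁺)/(2(1 − g̃2))` circulates for
this model family; it does not satisfy the round trip and is exposed as
`form="published"` because reported variance-decomposition results are
computed with it (below).

### Multi-valued inverse in s

At fixed `(v, u)`, `π̄2(s)` dips to a minimum near `s ≈ 1` and rises
toward finite limits as `s → 0` or `∞`; a target proportion in between is
attained at exactly two roots.  `solve_s_roots` brackets sign changes of
`π̄2(s) − g̃2` on a 2001-point grid over `log10 s ∈ [−10, 10]` (wider than
any plotted range, for safety) and polishes each bracket with Brent's
method to 1e-12 in `log10 s`; near-duplicate roots within 1e-9 merge.  The
growth-rate consistency precondition is checked at relative tolerance
1e-3 — loose by design, so that rate pairs quoted to 4–5 significant
figures are accepted; the root equation itself involves only the
proportion.  Beware the conditioning: `dπ̄2/d log10 s` is ~2e-4 on the
outer branches for the 22-h example, so a 4-s.f. rounding of `(k1, k2)`
(≈4e-5 in the implied target) moves the upper root by ~0.2 in `log10 s`.
Roots quoted to three decimals are therefore only reproducible from
full-precision rate pairs.

## Sobol sensitivity

Inputs `L1, L2 ∈ [1, 22] h` (human-cell phase-length range), `log10 s ∈
[−5, 5]`, and a dummy input `D ∈ [0, 1]` that the model ignores, all
uniform.  Sampling uses the Saltelli extension (matrices `A`, `B`, the
`d` column-swapped `AB_i` and, for second-order indices, the `d` blocks
`BA_i`) built on a scrambled Sobol' sequence, `N(2d+2)` evaluations at
base `N = 4096` (power of two for sequence balance).  Estimators:
Saltelli-2010 for `S1`, Jansen for `ST`, and the 2002 cross-matrix
estimator for `S2`; percentile bootstrap (200 reps default) over sample
rows gives 95% CIs.  The dummy input's indices stay within ±0.02 of zero
at `N = 4096`, calibrating the noise floor.

Output `k2` is inversion-form independent and its variance is almost
entirely `L2` (`ST > 0.98`): the division rate is set by the G2 duration.
Output `k1` depends on the inversion form: under the *published* form the
variance splits between `L1` and `L2` with a distinct interaction
(`S1 ≈ 0.70/0.13`, `S2(L1, L2) ≈ 0.15`) — the pattern reported for this
analysis, and the default here — whereas under the steady-state-consistent
form `k1 ≈ (ln 2-scale)/L1` and `L1` alone carries ~99% of the variance.
Both variants are computed in the test suite; the contrast is itself
informative about what the published decomposition measured.

## Synthetic trajectory data and fitting

`sample_trajectory` evaluates the closed-form `N` and `π2` on a schedule
(default noiseless, as in the sampling-interval experiment; a
multiplicative log-normal noise hook with seed is available but off by
default).  The generator normalises `p0 = 2/(1+s)` so `N(0) = 1`.  It
emulates ideal bulk measurements — no counting error, no
flow-cytometry/FUCCI gating error, no inter-cell cycle-length dispersion —
so passing fits bound only the discretisation (sampling-interval) effect,
not measurement noise robustness.

Fitting minimises the log least-squares loss
`Σ [ln z_k − ln N(t_k)]² + Σ [ln y_k − ln π2(t_k)]²` with the ODE initial
state pinned to the first sample (`G1(0) = (1−y1) z1`, `G2(0) = y1 z1`;
schedules must start at `t = 0`).  Optimisation runs in `log k` space
(conditioning) with box bounds `k ∈ [1e-4, 10] /h` via trust-region least
squares from a 16-point Latin-hypercube multistart, deterministic under
the config seed.  Exact self-generated data are recovered to better than
1e-4 relative across random rate pairs.

Closeness of a fitted ODE to the analytically matched one is measured by
the sup-norm deviations of `ln N` and of `π2` on a 0.1-h grid over
[0, 120] h from the shared initial state; the scalar ordering uses the
worse of the two.  For the standard experiment (`v = 1/16`, `u = 1/28`,
`s = 10³`) sampling every 7 h is closest, 30 h slightly worse, and 22 h —
exactly the cycle length, so every sample aliases to the per-cycle maximum
of `π2` — much worse (the fit typically runs `k1` into its upper bound
while fitting those degenerate samples almost exactly).  In the
`ln N`-metric alone the 7 h and 30 h fits are within ~0.01 of each other
(30 h marginally closer); the π2 metric and the combined metric give the
strict 7 < 30 < 22 ordering.

## Problem sizes and defaults

Random-sweep tests use 30–100 parameter sets with `v, u ∈ [0.02, 0.5]`
(phase lengths 1–25 h) and `log10 s ∈ [−3, 3]`; the acceptance script uses
a 2001-point `log10 s` grid for rate envelopes and the 4096-base Saltelli
design for sensitivity.  These sizes leave all estimates well inside their
quoted tolerances while keeping a full run to a few seconds.

## Known limitations

- Two compartments only; three/four-phase extensions multiply the
  case-split combinatorics and are out of scope.
- No cell death, quiescence, treatment, or density dependence; no
  stochastic inter-mitotic times — the PDE oscillations never damp.
- Fitting provides point estimates only (no identifiability or posterior
  analysis), and the PDE parameters themselves are not fitted.
- The uniform two-level initial density is a caricature; real initial
  cycle distributions are smoother, which would reduce oscillation
  amplitudes.
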