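# cyclepop

Analytical comparison of two minimal models of a proliferating cell
population structured by cell-cycle phase:

- a **maturity-structured transport PDE**: cells carry a position
  `φ ∈ [0, 1]` in the cycle and advance at piecewise-constant velocity
  (`v` through G1 on `[0, 1/2]`, `u` through the combined S/G2/M
  compartment — called "G2" — on `(1/2, 1]`); division at `φ = 1` returns
  two daughters to `φ = 0` (flux condition `v p(0,t) = 2 u p(1,t)`);
- a **two-compartment linear ODE**: `G1' = 2 k2 G2 − k1 G1`,
  `G2' = k1 G1 − k2 G2`.

The PDE has an exact method-of-characteristics solution (piecewise-constant
density with at most four pieces), so every observable an experimentalist
would record — the total count `N(t)`, the G2 proportion `π2(t)`, the
per-capita growth rate `β(t) = N'(t)/N(t)` — is available in closed form.
These observables are periodic with the inter-mitotic time
`η1 = 1/(2v) + 1/(2u)` and the population doubles exactly once per period,
so `β̄ = ln 2 / η1`.  The ODE instead shows asynchronous exponential
growth: `N ~ exp(λ⁺ t)` with a steady G2 proportion `g̃2`.

The package implements the full analysis pipeline around this pair:

1. **Matching** — equate the cycle averages of the PDE with the long-term
   ODE observables, `λ⁺(k1, k2) = β̄(v, u) = 2uv ln2/(u+v)` and
   `g̃2(k1, k2) = π̄2(v, u, s)`, giving a map `(v, u, s) → (k1, k2)`
   (`s = q0/p0` is the initial G2:G1 ratio).  The inverse is multi-valued:
   for fixed `(v, u)` two initial ratios `s1 ≠ s2` typically produce the
   same rate pair (`solve_s_roots`), although their full PDE dynamics —
   in particular the oscillation amplitude of `π2` — differ strongly.
2. **Global sensitivity** — Sobol indices (Saltelli design with
   second-order blocks, dummy-input negative control) of the matched rates
   with respect to the phase durations `L1 = 1/(2v)`, `L2 = 1/(2u)` and
   `log10 s`.
3. **Fitting** — calibrate `(k1, k2)` to discretely sampled `(N, π2)`
   trajectories by nonlinear least squares on log residuals, and measure
   how the sampling interval (relative to the 22-h cycle) degrades the fit.

## Worked example

The realistic human cell cycle used throughout: 22 h total, 8 h G1 and
14 h G2, i.e. `v = 1/16`, `u = 1/28` per hour.

```python
from cyclepop import (PDEParams, match_forward, oscillation_extrema,
                      sample_trajectory, SamplingSchedule,
                      ODETrajectoryModel, FitConfig)

m = match_forward(1/16, 1/28, 10**-0.605)
print(f"k1 = {m.k1:.5f}  k2 = {m.k2:.5f}  "
      f"(mean beta {m.mean_beta:.5f}, mean pi2 {m.mean_pi2:.5f})")
# k1 = 0.11455  k2 = 0.05542  (mean beta 0.03151, mean pi2 0.56856)
```

`k1, k2` are the compartment ODE rates whose long-term growth rate
(`0.03151 /h = ln2/22`) and steady G2 proportion (`0.56856`) equal the PDE
cycle averages.  The same pair is produced by the second root
`s = 10^2.645` — the average behaviour cannot identify the initial
condition — but the two roots oscillate very differently:

```python
ext = oscillation_extrema(PDEParams.from_ratio(1/16, 1/28, 10**-0.605))
print(ext.amplitude, ext.t_max, ext.t_min)   # 0.6115 14.0 0.0
```

the G2 proportion swings peak-to-peak by 0.61 within each cycle, peaking
14 h (= `1/(2u)`) after each division wave.  Fitting the ODE to PDE
samples taken every 7 h over 120 h (`s = 10^3`):

```python
params = PDEParams.from_ratio(1/16, 1/28, 1e3)
data = sample_trajectory(params, SamplingSchedule(interval=7.0, horizon=120.0))
res = ODETrajectoryModel(data, FitConfig(seed=0)).fit(matched_reference=(m.k1, m.k2))
print(res.summary())
```

```
ODE trajectory fit (log least squares)
==============================================
observations (time points)                  18
k1 (G1 -> G2 rate, /h)                0.099214
k2 (G2 -> division rate, /h)          0.062205
loss at optimum                        2.42262
converged                                 True
residual evaluations                       166
multistart points                           16
|k1 - k1_matched|                    0.0153319
|k2 - k2_matched|                   0.00679009
```

The 7-h fit lands near the analytically matched rates; sampling every 22 h
instead aliases the oscillation (every sample sits at the per-cycle maximum
of `π2`) and the fitted ODE drifts far from the matched one.

A CLI mirrors the library (`cyclepop match`, `invert`, `roots`,
`sensitivity`, `simulate-pde`, `simulate-ode`, `sample`, `fit`,
`figures`); `cyclepop figures` regenerates all standard plots.

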