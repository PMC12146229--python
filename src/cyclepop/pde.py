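"""Phase-structured transport model of a proliferating cell population.

A population of cycling cells is described by a density ``p(phi, t)`` over a
maturity coordinate ``phi`` on [0, 1] (phi = 0 birth, phi = 1 division).
Cells advance at a piecewise-constant velocity: ``v`` through G1
(phi in [0, 1/2]) and ``u`` through the combined S/G2/M compartment
(phi in (1/2, 1]), referred to as "G2" throughout.  Division at phi = 1
returns two daughters to phi = 0, giving the boundary flux condition
``v p(0, t) = 2 u p(1, t)``.  With uniform initial densities ``p0`` (G1) and
``q0 = s p0`` (G2), the method of characteristics yields a piecewise-constant
density at every time, and all population observables — phase counts, the
G2 proportion ``pi2(t)``, the total count ``N(t)`` and the per-capita growth
rate ``beta(t)`` — are available in closed form.  They are periodic with
period ``eta1 = 1/(2v) + 1/(2u)``, the inter-mitotic time, with the
population exactly doubling each period.

Times are in hours, rates in per hour, and phi is dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

__all__ = [
    "PDEParams",
    "PhaseSchedule",
    "DensityProfile",
    "PhaseState",
    "CycleSummary",
    "CellCyclePDE",
    "phase_schedule",
    "density",
    "phase_counts",
    "total_population",
    "log_total_population",
    "growth_rate",
    "mean_growth_rate",
    "mean_g2_closed_form",
    "mean_g2_quadrature",
    "oscillation_extrema",
    "initial_growth_ordering",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class PDEParams:
    """Parameters of the structured model.

    v, u : progression velocities through G1 and G2 (phi-units per hour).
    p0, q0 : uniform initial densities in G1 and G2 (cells per phi-unit).

    The initial phase ratio ``s = q0 / p0`` controls where the population
    starts in the cycle; observables that are proportions depend on the
    initial condition only through ``s``.
    """

    v: float
    u: float
    p0: float = 1.0
    q0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.v > 0 and self.u > 0):
            raise ValueError(f"progression velocities must be positive, got v={self.v}, u={self.u}")
        if self.p0 < 0 or self.q0 < 0:
            raise ValueError("initial densities must be non-negative")
        if self.p0 + self.q0 <= 0:
            raise ValueError("initial population must be positive")

    @classmethod
    def from_ratio(cls, v: float, u: float, s: float) -> "PDEParams":
        """Build parameters from the initial phase ratio ``s = q0/p0``,
        normalised so the initial total count is one cell."""
        if s <= 0:
            raise ValueError(f"initial phase ratio s must be positive, got {s}")
        return cls(v=v, u=u, p0=2.0 / (1.0 + s), q0=2.0 * s / (1.0 + s))

    @property
    def s(self) -> float:
        if self.p0 == 0:
            raise ValueError("s undefined when p0 = 0")
        return self.q0 / self.p0

    @property
    def schedule(self) -> "PhaseSchedule":
        return PhaseSchedule(L1=1.0 / (2.0 * self.v), L2=1.0 / (2.0 * self.u))


@dataclass(frozen=True)
class PhaseSchedule:
    """Phase durations implied by the velocities: L1 = 1/(2v), L2 = 1/(2u)."""

    L1: float
    L2: float

    @property
    def eta1(self) -> float:
        """Cell-cycle duration (hours)."""
        return self.L1 + self.L2

    def k_of_t(self, t):
        """Number of completed cycles at time t."""
        return np.floor(np.asarray(t, dtype=float) / self.eta1).astype(int)

    def tau_of_t(self, t):
        """Within-cycle time, t - k(t)*eta1, in [0, eta1)."""
        t = np.asarray(t, dtype=float)
        return t - np.floor(t / self.eta1) * self.eta1


@dataclass(frozen=True)
class DensityProfile:
    """Piecewise-constant cell density over phi in [0, 1] at a fixed time.

    ``values[i]`` holds on the half-open interval
    [breakpoints[i], breakpoints[i+1]); jump points take the right-limit.
    """

    t: float
    breakpoints: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", vals)
        if bp.ndim != 1 or vals.shape != (bp.size - 1,):
            raise ValueError("breakpoints/values shape mismatch")

    def __call__(self, phi):
        """Evaluate the density at phi (right-continuous)."""
        idx = np.clip(np.searchsorted(self.breakpoints, phi, side="right") - 1, 0, self.values.size - 1)
        return self.values[idx]

    def integral(self, lo: float = 0.0, hi: float = 1.0) -> float:
        """Integrate the density over [lo, hi] exactly."""
        a = np.maximum(self.breakpoints[:-1], lo)
        b = np.minimum(self.breakpoints[1:], hi)
        return float(np.sum(np.clip(b - a, 0.0, None) * self.values))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"phi_lo": self.breakpoints[:-1], "phi_hi": self.breakpoints[1:], "density": self.values}
        )


@dataclass(frozen=True)
class PhaseState:
    """Phase-resolved population state at one time."""

    t: float
    pG1: float
    pG2: float

    @property
    def N(self) -> float:
        return self.pG1 + self.pG2

    @property
    def pi1(self) -> float:
        return self.pG1 / self.N

    @property
    def pi2(self) -> float:
        return self.pG2 / self.N


@dataclass(frozen=True)
class CycleSummary:
    """Cycle-averaged growth rate and G2 proportion, and the within-cycle
    oscillation extrema of the G2 proportion."""

    mean_beta: float
    mean_pi2: float
    amplitude: float
    t_max: float
    t_min: float
    pi2_max: float
    pi2_min: float


# ---------------------------------------------------------------------------
# closed-form building blocks (vectorised over time / parameters)
# ---------------------------------------------------------------------------


def _counts_arrays(v, u, p0, q0, t):
    """Vectorised (N, pi2) with the 2^k cycle factor left OUT of N.

    Returns (k, N_within, pi2): N(t) = 2**k * N_within.
    """
    v, u, p0, q0, t = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (v, u, p0, q0, t))
    )
    L1, L2 = 1.0 / (2.0 * v), 1.0 / (2.0 * u)
    eta1 = L1 + L2
    k = np.floor(t / eta1)
    tau = t - k * eta1
    mn, mx = np.minimum(L1, L2), np.maximum(L1, L2)

    # Total count: one kink at tau = L2 = 1/(2u) regardless of phase ordering.
    N = np.where(
        tau < L2,
        0.5 * (p0 + q0) + u * q0 * tau,
        q0 + (0.5 - v / (2.0 * u)) * p0 + v * p0 * tau,
    )
    # G2 count, by region of the piecewise solution.
    early = 0.5 * q0 + (p0 * v - q0 * u) * tau
    late = (v / (2.0 * u) + 0.5) * p0 - (u / v) * q0 + (2.0 * u * q0 - v * p0) * tau
    mid_vu = 0.5 * (p0 + q0) - (u / v) * q0 + u * q0 * tau  # v > u, L1 <= tau < L2
    mid_uv = (v / (2.0 * u)) * p0 * np.ones_like(tau)  # u > v, L2 <= tau < L1
    g2 = np.where(
        tau < mn, early, np.where(tau >= mx, late, np.where(v > u, mid_vu, mid_uv))
    )
    return k, N, g2 / N


def _stable_segment_integral(a, b, c, d, t0, t1):
    """Integral of (a + b t)/(c + d t) over [t0, t1], elementwise.

    Uses the log closed form when ``d (t1-t0) / (c + d t0)`` is O(1) and a
    power series otherwise, avoiding the 1/d cancellation at small effective
    slope (which occurs for extreme initial phase ratios).
    """
    a, b, c, d, t0, t1 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (a, b, c, d, t0, t1))
    )
    A = a + b * t0
    C = c + d * t0
    D = t1 - t0
    y = d * D / C
    out = np.empty_like(A)

    small = np.abs(y) < 0.5
    if small.any():
        As, Bs, Cs, Ds, ys = A[small], b[small], C[small], D[small], y[small]
        tot = np.zeros_like(As)
        yn = np.ones_like(As)  # (-y)^n
        for n in range(80):
            term = yn * (Ds / Cs) * (As / (n + 1) + Bs * Ds / (n + 2))
            tot += term
            yn *= -ys
            if np.max(np.abs(term)) <= 1e-18 * max(float(np.max(np.abs(tot))), 1e-300):
                break
        out[small] = tot
    big = ~small
    if big.any():
        Ab, Bb, Cb, Db, db, yb = A[big], b[big], C[big], D[big], d[big], y[big]
        out[big] = (Bb / db) * Db + (Ab - Bb * Cb / db) / db * np.log1p(yb)
    return out


def _mean_g2_arrays(v, u, s):
    """Vectorised closed-form cycle average of the G2 proportion.

    pi2(t) is a rational function (a + b tau)/(c + d tau) on each of at most
    three within-cycle segments; each segment integrates exactly.
    """
    v, u, s = np.broadcast_arrays(*(np.asarray(x, dtype=float) for x in (v, u, s)))
    L1, L2 = 1.0 / (2.0 * v), 1.0 / (2.0 * u)
    eta1 = L1 + L2
    mn, mx = np.minimum(L1, L2), np.maximum(L1, L2)
    zero = np.zeros_like(v)

    total = _stable_segment_integral(0.5 * s, v - s * u, 0.5 * (1 + s), s * u, zero, mn)
    mid = np.zeros_like(total)
    m1 = v > u
    if m1.any():
        mid[m1] = _stable_segment_integral(
            0.5 * (1 + s[m1]) - (u[m1] / v[m1]) * s[m1],
            s[m1] * u[m1],
            0.5 * (1 + s[m1]),
            s[m1] * u[m1],
            L1[m1],
            L2[m1],
        )
    m2 = u > v
    if m2.any():
        mid[m2] = _stable_segment_integral(
            v[m2] / (2 * u[m2]),
            np.zeros_like(v[m2]),
            s[m2] + 0.5 - v[m2] / (2 * u[m2]),
            v[m2],
            L2[m2],
            L1[m2],
        )
    total = total + mid
    total = total + _stable_segment_integral(
        (v / (2 * u) + 0.5) - (u / v) * s, 2 * u * s - v, s + 0.5 - v / (2 * u), v, mx, eta1
    )
    return total / eta1


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def phase_schedule(params: PDEParams) -> PhaseSchedule:
    """Phase durations and cycle length implied by the velocities."""
    return params.schedule


def density(params: PDEParams, t: float) -> DensityProfile:
    """The piecewise-constant density profile p(phi, t); zero-width pieces
    are dropped.  Doubles exactly from one cycle to the next."""
    if t < 0:
        raise ValueError("t must be non-negative")
    v, u, p0, q0 = params.v, params.u, params.p0, params.q0
    sched = params.schedule
    L1, L2, eta1 = sched.L1, sched.L2, sched.eta1
    k = int(t // eta1)
    tau = t - k * eta1
    P = 2.0**k

    if tau < min(L1, L2):
        bp = [0.0, v * tau, 0.5, u * tau + 0.5, 1.0]
        vals = [2 * P * q0 * u / v, P * p0, P * p0 * v / u, P * q0]
    elif v > u and tau < L2:
        bp = [0.0, 0.5, u * tau + 0.5 - u / (2 * v), u * tau + 0.5, 1.0]
        vals = [2 * P * q0 * u / v, 2 * P * q0, P * p0 * v / u, P * q0]
    elif u > v and tau < L1:
        bp = [0.0, v * tau - v / (2 * u), v * tau, 0.5, 1.0]
        vals = [2 * P * p0, 2 * P * q0 * u / v, P * p0, P * p0 * v / u]
    else:
        bp = [0.0, v * tau - v / (2 * u), 0.5, u * tau + 0.5 - u / (2 * v), 1.0]
        vals = [2 * P * p0, 2 * P * q0 * u / v, 2 * P * q0, P * p0 * v / u]

    bp = np.asarray(bp)
    vals = np.asarray(vals)
    keep = np.diff(bp) > 1e-15
    # merge breakpoints of zero-width pieces
    out_bp = [bp[0]]
    out_vals = []
    for i, kp in enumerate(keep):
        if kp:
            out_bp.append(bp[i + 1])
            out_vals.append(vals[i])
    return DensityProfile(t=t, breakpoints=np.asarray(out_bp), values=np.asarray(out_vals))


def phase_counts(params: PDEParams, t: float) -> PhaseState:
    """Closed-form phase counts at time t (equal to the density integrals
    over [0, 1/2) and [1/2, 1))."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be non-negative")
    k, N, pi2 = _counts_arrays(params.v, params.u, params.p0, params.q0, t)
    scale = 2.0**k
    total = scale * N
    return PhaseState(t=float(t), pG1=float(total * (1 - pi2)), pG2=float(total * pi2))


def total_population(params: PDEParams, t) -> float | np.ndarray:
    """Total cell count N(t); vectorised over t."""
    k, N, _ = _counts_arrays(params.v, params.u, params.p0, params.q0, t)
    out = 2.0**k * N
    return float(out) if np.isscalar(t) else out


def log_total_population(params: PDEParams, t) -> float | np.ndarray:
    """ln N(t), computed without forming 2^k (safe for very large t)."""
    k, N, _ = _counts_arrays(params.v, params.u, params.p0, params.q0, t)
    out = k * LN2 + np.log(N)
    return float(out) if np.isscalar(t) else out


def g2_proportion(params: PDEParams, t) -> float | np.ndarray:
    """G2 phase proportion pi2(t); vectorised over t. Periodic in eta1 and
    independent of p0 at fixed s."""
    _, _, pi2 = _counts_arrays(params.v, params.u, params.p0, params.q0, t)
    return float(pi2) if np.isscalar(t) else pi2


def growth_rate(params: PDEParams, t) -> float | np.ndarray:
    """Per-capita growth rate beta(t) = N'(t)/N(t) (right-limit at the
    within-cycle switch point and at cycle boundaries)."""
    v, u, p0, q0 = params.v, params.u, params.p0, params.q0
    sched = params.schedule
    tau = sched.tau_of_t(t)
    L2 = sched.L2
    num = np.where(tau < L2, u * q0, v * p0)
    den = np.where(
        tau < L2,
        0.5 * (p0 + q0) + u * q0 * tau,
        q0 + (0.5 - v / (2.0 * u)) * p0 + v * p0 * tau,
    )
    out = num / den
    return float(out) if np.isscalar(t) else out


def mean_growth_rate(params: PDEParams) -> float:
    """Cycle-averaged growth rate: ln(2)/eta1, independent of s and of how
    the cycle splits into phases."""
    return LN2 / params.schedule.eta1


def mean_g2_closed_form(params: PDEParams) -> float:
    """Closed-form cycle average of the G2 proportion (exact per-segment
    integration of the piecewise rational pi2(t))."""
    s = params.s
    if s <= 0:
        raise ValueError("mean G2 proportion requires a positive initial ratio s")
    return float(_mean_g2_arrays(params.v, params.u, s))


def mean_g2_quadrature(params: PDEParams) -> float:
    """Cycle average of pi2 by adaptive quadrature; oracle for the closed form."""
    sched = params.schedule
    pts = sorted({0.0, min(sched.L1, sched.L2), max(sched.L1, sched.L2), sched.eta1})
    total = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        if b - a <= 0:
            continue
        val, _ = quad(
            lambda tt: g2_proportion(params, float(tt)), a, b, epsabs=1e-13, epsrel=1e-12, limit=200
        )
        total += val
    return total / sched.eta1


def oscillation_extrema(params: PDEParams) -> CycleSummary:
    """Within-cycle extrema of pi2 and the peak-to-peak amplitude.

    pi2 is continuous and monotone between the kinks of the piecewise
    solution, so the extrema over one period lie in {0, L1, L2} (the period
    endpoint repeats t=0).  Ties resolve to the earliest attaining time.
    """
    sched = params.schedule
    cands = sorted({0.0, sched.L1, sched.L2})
    vals = [(tc, float(g2_proportion(params, tc))) for tc in cands]
    t_max, pi_max = max(vals, key=lambda z: (z[1], -z[0]))
    t_min, pi_min = min(vals, key=lambda z: (z[1], z[0]))
    return CycleSummary(
        mean_beta=mean_growth_rate(params),
        mean_pi2=mean_g2_closed_form(params) if params.p0 > 0 and params.q0 > 0 else float("nan"),
        amplitude=pi_max - pi_min,
        t_max=t_max,
        t_min=t_min,
        pi2_max=pi_max,
        pi2_min=pi_min,
    )


def initial_growth_ordering(params: PDEParams) -> bool:
    """True iff the first within-cycle growth segment is strictly the larger
    one, i.e. p0/L1 < s*p0/L2."""
    if params.p0 <= 0:
        raise ValueError("requires p0 > 0")
    sched = params.schedule
    return params.p0 / sched.L1 < params.s * params.p0 / sched.L2


class CellCyclePDE:
    """Convenience wrapper binding a parameter set to the closed-form
    observables.

    >>> model = CellCyclePDE.from_ratio(v=1/16, u=1/28, s=10**-0.605)
    >>> model.schedule.eta1
    22.0
    """

    def __init__(self, params: PDEParams):
        self.params = params

    @classmethod
    def from_ratio(cls, v: float, u: float, s: float) -> "CellCyclePDE":
        return cls(PDEParams.from_ratio(v, u, s))

    @property
    def schedule(self) -> PhaseSchedule:
        return self.params.schedule

    def density(self, t: float) -> DensityProfile:
        return density(self.params, t)

    def phase_counts(self, t: float) -> PhaseState:
        return phase_counts(self.params, t)

    def total_population(self, t):
        return total_population(self.params, t)

    def log_total_population(self, t):
        return log_total_population(self.params, t)

    def g2_proportion(self, t):
        return g2_proportion(self.params, t)

    def growth_rate(self, t):
        return growth_rate(self.params, t)

    def mean_growth_rate(self) -> float:
        return mean_growth_rate(self.params)

    def mean_g2(self, method: str = "closed_form") -> float:
        if method == "closed_form":
            return mean_g2_closed_form(self.params)
        if method == "quadrature":
            return mean_g2_quadrature(self.params)
        raise ValueError(f"unknown method {method!r}")

    def oscillation_extrema(self) -> CycleSummary:
        return oscillation_extrema(self.params)

    def timeseries(self, times) -> "pd.DataFrame":  # noqa: F821
        """DataFrame of (t, N, pi2) at the given times."""
        import pandas as pd

        times = np.asarray(times, dtype=float)
        return pd.DataFrame(
            {
                "t": times,
                "N": total_population(self.params, times),
                "pi2": g2_proportion(self.params, times),
            }
        )
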