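"""Matching the structured PDE to the two-compartment ODE.

The models are linked by equating the ODE's long-term observables with the
PDE's cycle averages:

    lambda_plus(k1, k2) = beta_bar(v, u) = 2 u v ln(2)/(u + v)
    g2_star(k1, k2)     = pi2_bar(v, u, s)

The forward map (v, u, s) -> (k1, k2) is single-valued; the inverse is not:
fixing (k1, k2) pins (v, u) to the iso-growth curve and typically admits two
initial-ratio roots s with the same cycle-averaged G2 proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .ode import ODEParams, invert_long_term, long_term_growth, steady_g2
from .pde import LN2, PDEParams, _mean_g2_arrays, mean_g2_closed_form

__all__ = [
    "MatchResult",
    "SRootSet",
    "mean_beta",
    "match_forward",
    "iso_growth_u",
    "solve_s_roots",
    "verify_theorem1",
]


@dataclass(frozen=True)
class MatchResult:
    """Matched ODE rates and the PDE averages they reproduce."""

    k1: float
    k2: float
    mean_beta: float
    mean_pi2: float

    @property
    def residuals(self) -> tuple[float, float]:
        return (
            abs(long_term_growth((self.k1, self.k2)) - self.mean_beta),
            abs(steady_g2((self.k1, self.k2)) - self.mean_pi2),
        )

    @property
    def ode_params(self) -> ODEParams:
        return ODEParams(k1=self.k1, k2=self.k2)


@dataclass(frozen=True)
class SRootSet:
    """Initial-ratio roots matching a target steady proportion."""

    roots: tuple[float, ...]
    bracket: tuple[float, float]
    target_g2: float

    @property
    def log10_roots(self) -> tuple[float, ...]:
        return tuple(math.log10(r) for r in self.roots)


def mean_beta(v: float, u: float) -> float:
    """Cycle-averaged PDE growth rate, 2uv ln2/(u+v) = ln2/eta1."""
    return 2.0 * u * v * LN2 / (u + v)


def match_forward(v: float, u: float, s: float, form: str = "consistent") -> MatchResult:
    """Map PDE parameters to the matched ODE rates."""
    params = PDEParams.from_ratio(v, u, s)
    beta = mean_beta(v, u)
    pi2 = mean_g2_closed_form(params)
    ode = invert_long_term(beta, pi2, form=form)
    return MatchResult(k1=ode.k1, k2=ode.k2, mean_beta=beta, mean_pi2=pi2)


def iso_growth_u(k1: float, k2: float, v: float) -> float:
    """The G2 velocity u on the iso-growth curve beta_bar(v, u) = lambda_plus.

    Solving 2uv ln2/(u+v) = lambda_plus for u requires
    v > lambda_plus/(2 ln 2) (the curve's vertical asymptote).
    """
    lam = long_term_growth((k1, k2))
    denom = 2.0 * LN2 * v - lam
    if denom <= 0:
        raise ValueError(
            f"no positive u exists: v={v} is at or below the asymptote {lam / (2 * LN2):.6g}"
        )
    return lam * v / denom


def solve_s_roots(
    v: float,
    u: float,
    k1: float,
    k2: float,
    log10_bracket: tuple[float, float] = (-10.0, 10.0),
    grid_points: int = 2001,
    growth_rtol: float = 1e-3,
) -> SRootSet:
    """All initial ratios s whose cycle-averaged G2 proportion equals the
    steady proportion of (k1, k2), searched over log10(s).

    The growth rates must already be consistent: lambda_plus(k1, k2) is
    compared with beta_bar(v, u) at relative tolerance ``growth_rtol``
    (loose enough to accept rate pairs quoted to a few significant figures;
    the proportion equation does not involve the growth rate).
    """
    lam = long_term_growth((k1, k2))
    beta = mean_beta(v, u)
    if abs(lam - beta) > growth_rtol * beta:
        raise ValueError(
            f"growth rates inconsistent: lambda_plus={lam:.6g} vs mean beta={beta:.6g}"
        )
    target = steady_g2((k1, k2))

    lo, hi = log10_bracket
    grid = np.linspace(lo, hi, grid_points)
    f = lambda ls: float(_mean_g2_arrays(v, u, 10.0**ls)) - target
    vals = np.array([f(x) for x in grid])

    roots: list[float] = []
    for i in range(grid_points - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(grid[i])
        elif a * b < 0:
            roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-12))
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    # merge near-duplicates in log10(s)
    merged: list[float] = []
    for r in sorted(roots):
        if not merged or r - merged[-1] > 1e-9:
            merged.append(r)
    return SRootSet(
        roots=tuple(10.0**r for r in merged), bracket=(lo, hi), target_g2=target
    )


def verify_theorem1(v: float, u: float, s1: float, s2: float, tol: float = 1e-9) -> bool:
    """Equal matched k1 at two initial ratios implies equal matched k2.

    At fixed (v, u) the growth rate match pins lambda_plus, which makes k2 a
    function of k1 alone; this checks the implication numerically.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("initial ratios must be positive")
    m1 = match_forward(v, u, s1)
    m2 = match_forward(v, u, s2)
    if abs(m1.k1 - m2.k1) > tol:
        return True  # antecedent false: implication vacuously holds
    return abs(m1.k2 - m2.k2) <= tol
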