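"""Two-compartment linear ODE model of cell-cycle progression.

Cells move from G1 to G2 at rate k1 and divide out of G2 at rate k2, each
division returning two daughters to G1:

    dG1/dt = 2 k2 G2 - k1 G1
    dG2/dt =   k1 G1 - k2 G2

The system exhibits asynchronous exponential growth: the total count N grows
like exp(lambda_plus t) while the G2 proportion g2 settles to the steady
value g2_star, the positive root of k1 - (k1+k2) g - k2 g^2 = 0.  The
long-term growth rate satisfies lambda_plus = k2 * g2_star.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ODEParams",
    "ODELongTerm",
    "TwoCompartmentODE",
    "ode_solve",
    "steady_g2",
    "long_term_growth",
    "invert_long_term",
]


@dataclass(frozen=True)
class ODEParams:
    """Compartment transition rates (per hour)."""

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (self.k1 > 0 and self.k2 > 0):
            raise ValueError(f"rates must be positive, got k1={self.k1}, k2={self.k2}")


@dataclass(frozen=True)
class ODELongTerm:
    """Long-term observables: steady G2 proportion and growth rate."""

    g2_star: float
    lambda_plus: float


def _as_params(params) -> ODEParams:
    if isinstance(params, ODEParams):
        return params
    k1, k2 = params
    return ODEParams(k1=float(k1), k2=float(k2))


def steady_g2(params) -> float:
    """Steady-state G2 proportion: the root in (0, 1) of the proportion
    dynamics dg2/dt = k1 - (k1+k2) g2 - k2 g2^2."""
    p = _as_params(params)
    k1, k2 = p.k1, p.k2
    disc = math.sqrt(k1 * k1 + 6.0 * k1 * k2 + k2 * k2)
    return (-(k1 + k2) + disc) / (2.0 * k2)


def long_term_growth(params) -> float:
    """Long-term per-capita growth rate lambda_plus = k2 * g2_star (the
    dominant eigenvalue of the rate matrix)."""
    p = _as_params(params)
    k1, k2 = p.k1, p.k2
    disc = math.sqrt(k1 * k1 + 6.0 * k1 * k2 + k2 * k2)
    return (-(k1 + k2) + disc) / 2.0


def long_term(params) -> ODELongTerm:
    return ODELongTerm(g2_star=steady_g2(params), lambda_plus=long_term_growth(params))


def invert_long_term(lambda_plus: float, g2_star: float, form: str = "consistent") -> ODEParams:
    """Rates (k1, k2) from observables (lambda_plus, g2_star).

    Always k2 = lambda_plus / g2_star.  Two algebraic forms for k1 are in
    circulation for this model family:

    - ``"consistent"`` (default): k1 = lambda_plus (1 + g2_star)/(1 - g2_star),
      the exact solution of the steady-state balance; composing with
      ``steady_g2``/``long_term_growth`` is the identity.
    - ``"published"``: k1 = (g2_star + 2 lambda_plus)/(2 (1 - g2_star)), a
      quoted variant that does not satisfy the roundtrip identity.  It is
      retained because reported variance-based sensitivity results for the
      matched rates are computed with it (see the sensitivity module).
    """
    if not lambda_plus > 0:
        raise ValueError("lambda_plus must be positive")
    if not (0.0 < g2_star < 1.0):
        raise ValueError(f"g2_star must lie in (0, 1), got {g2_star}")
    k2 = lambda_plus / g2_star
    if form == "consistent":
        k1 = lambda_plus * (1.0 + g2_star) / (1.0 - g2_star)
    elif form == "published":
        k1 = (g2_star + 2.0 * lambda_plus) / (2.0 * (1.0 - g2_star))
    else:
        raise ValueError(f"unknown inversion form {form!r}")
    return ODEParams(k1=k1, k2=k2)


def ode_solve(params, init, times) -> "pd.DataFrame":  # noqa: F821
    """Exact solution of the linear system by eigen-decomposition.

    Parameters
    ----------
    params : ODEParams or (k1, k2)
    init : (G1(0), G2(0)), non-negative with positive sum
    times : sequence of hours

    Returns a DataFrame with columns t, G1, G2, N, g1, g2.
    """
    import pandas as pd

    p = _as_params(params)
    G10, G20 = float(init[0]), float(init[1])
    if G10 < 0 or G20 < 0 or G10 + G20 <= 0:
        raise ValueError("initial counts must be non-negative with N(0) > 0")
    times = np.atleast_1d(np.asarray(times, dtype=float))

    M = np.array([[-p.k1, 2.0 * p.k2], [p.k1, -p.k2]])
    evals, V = np.linalg.eig(M)
    coef = np.linalg.solve(V, np.array([G10, G20]))
    sol = (V @ (coef[:, None] * np.exp(np.outer(evals, times)))).real
    G1, G2 = sol[0], sol[1]
    N = G1 + G2
    return pd.DataFrame({"t": times, "G1": G1, "G2": G2, "N": N, "g1": G1 / N, "g2": G2 / N})


class TwoCompartmentODE:
    """Convenience wrapper mirroring :class:`cyclepop.pde.CellCyclePDE`."""

    def __init__(self, params):
        self.params = _as_params(params)

    def solve(self, init, times):
        return ode_solve(self.params, init, times)

    def steady_g2(self) -> float:
        return steady_g2(self.params)

    def long_term_growth(self) -> float:
        return long_term_growth(self.params)

    def long_term(self) -> ODELongTerm:
        return long_term(self.params)
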