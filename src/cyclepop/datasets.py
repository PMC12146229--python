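"""Discrete trajectory datasets sampled from the structured PDE.

Emulates an experiment that records the total cell number N and the G2
phase proportion pi2 at a fixed sampling interval — the "synthetic PDE
data" used to calibrate the compartment ODE without knowledge of the
underlying PDE parameters.  Sampling is noiseless by default; an optional
multiplicative log-normal noise hook is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pde import PDEParams, g2_proportion, total_population

__all__ = [
    "SamplingSchedule",
    "TrajectoryDataset",
    "sample_trajectory",
    "read_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class SamplingSchedule:
    """Regular or explicit sampling times (hours).

    Either ``interval`` + ``horizon`` (times 0, dt, 2dt, ... <= horizon) or
    an explicit ascending ``times`` list.  Fitting assumes the first sample
    is at t = 0 (the initial phase split is read off the first point).
    """

    interval: float | None = None
    horizon: float | None = None
    start: float = 0.0
    times: tuple[float, ...] | None = None

    def resolve(self) -> np.ndarray:
        if self.times is not None:
            t = np.asarray(self.times, dtype=float)
            if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0) or np.any(t < 0):
                raise ValueError("explicit times must be non-negative and strictly ascending")
            return t
        if self.interval is None or self.horizon is None:
            raise ValueError("provide either explicit times or interval + horizon")
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        return np.arange(self.start, self.horizon + 1e-9, self.interval, dtype=float)


@dataclass(frozen=True)
class TrajectoryDataset:
    """Samples (t_k, z_k = N, y_k = pi2) of a population trajectory."""

    t: np.ndarray
    N: np.ndarray
    pi2: np.ndarray
    fit_ready: bool = True  # False when the schedule lacks a t=0 sample

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        N = np.asarray(self.N, dtype=float)
        y = np.asarray(self.pi2, dtype=float)
        if not (t.shape == N.shape == y.shape) or t.ndim != 1:
            raise ValueError("t, N, pi2 must be 1-d arrays of equal length")
        if np.any(N <= 0):
            raise ValueError("cell counts must be positive")
        if np.any((y <= 0) | (y > 1)):
            raise ValueError("G2 proportions must lie in (0, 1]")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "N", N)
        object.__setattr__(self, "pi2", y)

    def __len__(self) -> int:
        return self.t.size

    @property
    def initial_ratio(self) -> float:
        """s = G2(0)/G1(0) read off the first sample."""
        y0 = self.pi2[0]
        return y0 / (1.0 - y0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "N": self.N, "pi2": self.pi2})


def sample_trajectory(
    params: PDEParams,
    schedule: SamplingSchedule,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> TrajectoryDataset:
    """Sample N(t) and pi2(t) from the closed-form PDE solution.

    ``noise_sd`` is the standard deviation of multiplicative log-normal
    noise applied to both series (0 = exact samples); noisy proportions are
    clipped back into (0, 1].
    """
    times = schedule.resolve()
    fit_ready = times[0] == 0.0
    if not fit_ready:
        warnings.warn("schedule has no t=0 sample; dataset not suitable for fitting", stacklevel=2)
    N = total_population(params, times)
    y = g2_proportion(params, times)
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        N = N * np.exp(rng.normal(0.0, noise_sd, times.size))
        y = y * np.exp(rng.normal(0.0, noise_sd, times.size))
        y = np.clip(y, np.finfo(float).tiny, 1.0)
    return TrajectoryDataset(t=times, N=np.atleast_1d(N), pi2=np.atleast_1d(y), fit_ready=fit_ready)


def write_dataset(dataset: TrajectoryDataset, path: str | Path) -> None:
    """Write as CSV with header t,N,pi2 at full precision."""
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_dataset(path: str | Path) -> TrajectoryDataset:
    """Read a t,N,pi2 CSV; malformed or non-positive rows raise with the
    offending line named."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty dataset file") from None
    required = {"t", "N", "pi2"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns t,N,pi2, got {list(df.columns)}")
    if len(df) == 0:
        raise ValueError(f"{path}: dataset has no rows")
    for col in ("t", "N", "pi2"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy())[0]
        if bad.size:
            raise ValueError(f"{path}: malformed value in column {col!r} at line {bad[0] + 2}")
        df[col] = vals
    nonpos = np.nonzero((df["N"] <= 0).to_numpy())[0]
    if nonpos.size:
        raise ValueError(f"{path}: non-positive N at line {nonpos[0] + 2}")
    return TrajectoryDataset(
        t=df["t"].to_numpy(),
        N=df["N"].to_numpy(),
        pi2=df["pi2"].to_numpy(),
        fit_ready=float(df["t"].iloc[0]) == 0.0,
    )
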