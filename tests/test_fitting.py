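"""Log least-squares calibration of the compartment ODE to trajectory data."""

import numpy as np
import pytest

from cyclepop import (
    FitConfig,
    ODETrajectoryModel,
    PDEParams,
    SamplingSchedule,
    TrajectoryDataset,
    fit_ode,
    log_loss,
    match_forward,
    ode_solve,
    sample_trajectory,
    trajectory_deviation,
)


def ode_dataset(k1, k2, init=(0.7, 0.3), times=None):
    t = np.arange(0.0, 40.0, 1.0) if times is None else np.asarray(times, float)
    sol = ode_solve((k1, k2), init, t)
    return TrajectoryDataset(t=t, N=sol["N"].to_numpy(), pi2=sol["g2"].to_numpy())


def test_log_loss_zero_at_generating_parameters():
    data = ode_dataset(0.11455, 0.05541)
    assert log_loss(data, (0.11455, 0.05541)) < 1e-18
    assert log_loss(data, (0.2, 0.05)) > 0


def test_log_loss_invariant_to_count_rescaling():
    # doubling all counts rescales the initial condition taken from the first
    # sample, so log residuals are unchanged
    data = ode_dataset(0.3, 0.1)
    data2 = TrajectoryDataset(t=data.t, N=2.0 * data.N, pi2=data.pi2)
    assert log_loss(data2, (0.25, 0.12)) == pytest.approx(log_loss(data, (0.25, 0.12)), rel=1e-10)


def test_generative_self_recovery():
    data = ode_dataset(0.11455, 0.05541)
    res = fit_ode(data, FitConfig(seed=1))
    assert res.k1_hat == pytest.approx(0.11455, abs=1e-6)
    assert res.k2_hat == pytest.approx(0.05541, abs=1e-6)
    assert res.loss < 1e-16
    assert res.converged


def test_generative_recovery_sweep():
    rng = np.random.default_rng(12)
    for k1, k2 in 10.0 ** rng.uniform(-1.5, 0.3, (50, 2)):
        data = ode_dataset(k1, k2)
        res = fit_ode(data, FitConfig(multistart=4, seed=2))
        assert res.k1_hat == pytest.approx(k1, rel=1e-4)
        assert res.k2_hat == pytest.approx(k2, rel=1e-4)


def test_adding_exact_points_never_raises_optimum_loss():
    coarse = ode_dataset(0.2, 0.08, times=np.arange(0.0, 40.0, 8.0))
    fine = ode_dataset(0.2, 0.08, times=np.arange(0.0, 40.0, 2.0))
    loss_coarse = fit_ode(coarse, FitConfig(seed=3)).loss
    loss_fine = fit_ode(fine, FitConfig(seed=3)).loss
    assert loss_fine <= loss_coarse + 1e-12


def test_fit_requires_time_zero_and_enough_points():
    data = ode_dataset(0.2, 0.08)
    with pytest.raises(ValueError):
        ODETrajectoryModel(TrajectoryDataset(t=data.t[:2], N=data.N[:2], pi2=data.pi2[:2]))
    shifted = TrajectoryDataset(t=data.t[1:], N=data.N[1:], pi2=data.pi2[1:], fit_ready=False)
    with pytest.raises(ValueError):
        ODETrajectoryModel(shifted)


def test_fit_deterministic_under_seed():
    params = PDEParams.from_ratio(1 / 16, 1 / 28, 1e3)
    data = sample_trajectory(params, SamplingSchedule(interval=7.0, horizon=119.0))
    a = fit_ode(data, FitConfig(seed=7))
    b = fit_ode(data, FitConfig(seed=7))
    assert (a.k1_hat, a.k2_hat, a.loss) == (b.k1_hat, b.k2_hat, b.loss)


def test_summary_and_discrepancy_reporting():
    data = ode_dataset(0.3, 0.1)
    res = fit_ode(data, FitConfig(seed=1), matched_reference=(0.31, 0.1))
    assert res.discrepancy[0] == pytest.approx(0.01, abs=1e-4)
    text = res.summary()
    assert "k1" in text and "loss" in text


@pytest.fixture(scope="module")
def sampling_interval_fits():
    """Fits of PDE data (v=1/16, u=1/28, s=1e3) at several intervals,
    plus deviations from the analytically matched ODE."""
    v, u, s = 1 / 16, 1 / 28, 1e3
    params = PDEParams.from_ratio(v, u, s)
    m = match_forward(v, u, s)
    init = (1.0 / (1 + s), s / (1 + s))
    out = {}
    for interval in (1.0, 7.0, 22.0, 30.0):
        data = sample_trajectory(params, SamplingSchedule(interval=interval, horizon=120.0))
        res = ODETrajectoryModel(data, FitConfig(seed=0)).fit(matched_reference=(m.k1, m.k2))
        dev = trajectory_deviation((res.k1_hat, res.k2_hat), (m.k1, m.k2), init)
        out[interval] = (res, dev)
    return out


def test_cycle_aliased_sampling_gives_worst_fit(sampling_interval_fits):
    # sampling at the 22-h period sees only the oscillation maximum and the
    # fit drifts far from the matched ODE; 7-h sampling resolves the cycle
    _, dev7 = sampling_interval_fits[7.0]
    _, dev22 = sampling_interval_fits[22.0]
    assert dev7[0] < dev22[0]  # sup |Delta ln N|
    assert dev7[1] < dev22[1]  # sup |Delta pi2|


def test_interval_closeness_ordering(sampling_interval_fits):
    # closeness to the matched ODE (worst of the two sup-norms): 7 < 30 < 22
    closeness = {iv: max(dev) for iv, (_, dev) in sampling_interval_fits.items()}
    assert closeness[7.0] < closeness[30.0] < closeness[22.0]


def test_fast_sampling_intervals_agree(sampling_interval_fits):
    res1, _ = sampling_interval_fits[1.0]
    res7, _ = sampling_interval_fits[7.0]
    assert res1.k1_hat == pytest.approx(res7.k1_hat, rel=0.05)
    assert res1.k2_hat == pytest.approx(res7.k2_hat, rel=0.05)
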