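"""Closed-form structured-PDE solution and its derived observables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from cyclepop import (
    CellCyclePDE,
    PDEParams,
    density,
    g2_proportion,
    growth_rate,
    initial_growth_ordering,
    log_total_population,
    mean_g2_closed_form,
    mean_g2_quadrature,
    mean_growth_rate,
    oscillation_extrema,
    phase_counts,
    phase_schedule,
    total_population,
)
from conftest import random_parameter_sets

pde_triples = st.tuples(
    st.floats(0.02, 0.5), st.floats(0.02, 0.5), st.floats(-3.0, 3.0)
)


@pytest.mark.parametrize(
    "v,u,expected",
    [
        (1 / 16, 1 / 28, (8.0, 14.0, 22.0)),
        (1 / 22, 1 / 22, (11.0, 11.0, 22.0)),
        (0.04, 0.2, (12.5, 2.5, 15.0)),
    ],
)
def test_phase_schedule_durations(v, u, expected):
    sched = phase_schedule(PDEParams(v=v, u=u))
    assert (sched.L1, sched.L2, sched.eta1) == pytest.approx(expected)


@pytest.mark.parametrize("v,u", [(0.0, 0.1), (-1.0, 0.1), (0.1, 0.0)])
def test_invalid_velocities_rejected(v, u):
    with pytest.raises(ValueError):
        PDEParams(v=v, u=u)


def test_density_initial_condition():
    prof = density(PDEParams(v=1 / 16, u=1 / 28, p0=1.0, q0=3.0), 0.0)
    assert prof.breakpoints == pytest.approx([0.0, 0.5, 1.0])
    assert prof.values == pytest.approx([1.0, 3.0])


def test_density_profile_midcycle():
    # direct substitution into the early-cycle branch at t = 6 h
    prof = density(PDEParams(v=1 / 16, u=1 / 28, p0=1.0, q0=3.0), 6.0)
    assert prof.breakpoints == pytest.approx([0.0, 0.375, 0.5, 5 / 7, 1.0])
    assert prof.values == pytest.approx([2 * 3 * (16 / 28), 1.0, 28 / 16, 3.0])


def test_density_doubles_each_cycle():
    params = PDEParams(v=1 / 16, u=1 / 28, p0=1.0, q0=3.0)
    for t in (0.0, 3.0, 9.5, 17.0):
        a, b = density(params, t), density(params, t + 22.0)
        assert b.breakpoints == pytest.approx(a.breakpoints)
        assert b.values == pytest.approx(2.0 * a.values)


def test_division_flux_boundary_condition(param_sweep):
    # flux into birth equals twice the flux out of division: v p(0+) = 2 u p(1-)
    # (holds for every t > 0; the arbitrary initial profile need not obey it)
    for v, u, s in param_sweep:
        params = PDEParams.from_ratio(v, u, s)
        for t in (0.9, 1.7, 13.3, 40.1):
            prof = density(params, t)
            assert v * prof.values[0] == pytest.approx(2 * u * prof.values[-1], rel=1e-12)


def test_phase_counts_at_zero_and_one_period():
    params = PDEParams(v=1 / 16, u=1 / 28, p0=1.0, q0=3.0)
    st0 = phase_counts(params, 0.0)
    assert st0.N == pytest.approx(2.0)  # (p0+q0)/2
    assert st0.pi2 == pytest.approx(3 / 4)  # s/(1+s)
    assert phase_counts(params, 22.0).N == pytest.approx(2 * st0.N)


def test_phase_counts_match_density_integrals(param_sweep):
    rng = np.random.default_rng(7)
    for v, u, s in param_sweep:
        params = PDEParams.from_ratio(v, u, s)
        t = float(rng.uniform(0, 60))
        prof = density(params, t)
        state = phase_counts(params, t)
        assert state.N == pytest.approx(prof.integral(0, 1), rel=1e-10)
        assert state.pG2 == pytest.approx(prof.integral(0.5, 1), rel=1e-10)


def test_total_population_velocity_swap_agrees_at_period_multiples():
    # swapped (v,u) with equal cycle length produce identical N at multiples
    # of the period but different N in between
    pa = PDEParams.from_ratio(0.04, 0.2, 1.0)
    pb = PDEParams.from_ratio(0.2, 0.04, 1.0)
    for m in (1, 2, 3):
        assert total_population(pa, 15.0 * m) == pytest.approx(total_population(pb, 15.0 * m))
    assert total_population(pa, 7.0) != pytest.approx(total_population(pb, 7.0))


def test_growth_rate_periodic_and_averages_to_log2_over_period():
    params = PDEParams.from_ratio(1 / 16, 1 / 28, 0.7)
    eta1 = params.schedule.eta1
    t = np.linspace(0.1, eta1 - 0.1, 40)
    assert growth_rate(params, t + eta1) == pytest.approx(growth_rate(params, t))
    total = sum(
        quad(lambda tt: growth_rate(params, tt), a, b, epsabs=1e-13, epsrel=1e-12)[0]
        for a, b in ((0.0, 14.0), (14.0, eta1))
    )
    assert total / eta1 == pytest.approx(math.log(2) / eta1, abs=1e-10)


def test_initial_growth_segment_ordering():
    # first within-cycle segment grows faster iff p0/L1 < s p0/L2
    assert initial_growth_ordering(PDEParams.from_ratio(1 / 16, 1 / 28, 10**2.645))
    assert not initial_growth_ordering(PDEParams.from_ratio(1 / 16, 1 / 28, 14 / 8))
    assert not initial_growth_ordering(PDEParams.from_ratio(1 / 22, 1 / 22, 1.0))
    rate_first = growth_rate(PDEParams.from_ratio(1 / 16, 1 / 28, 10**2.645), 0.0)
    rate_last = growth_rate(PDEParams.from_ratio(1 / 16, 1 / 28, 10**2.645), 21.9)
    assert rate_first > rate_last


def test_mean_growth_rate_closed_form():
    assert mean_growth_rate(PDEParams(v=1 / 16, u=1 / 28)) == pytest.approx(math.log(2) / 22)
    assert mean_growth_rate(PDEParams(v=0.04, u=0.2)) == pytest.approx(math.log(2) / 15)
    # independent of s and of the L1/L2 split of the cycle
    assert mean_growth_rate(PDEParams.from_ratio(1 / 16, 1 / 28, 100.0)) == pytest.approx(
        mean_growth_rate(PDEParams.from_ratio(1 / 28, 1 / 16, 0.01))
    )


def test_mean_g2_closed_form_matches_quadrature(param_sweep):
    for v, u, s in param_sweep:
        params = PDEParams.from_ratio(v, u, s)
        assert mean_g2_closed_form(params) == pytest.approx(
            mean_g2_quadrature(params), abs=1e-8
        )


def test_mean_g2_reproduces_matched_rate_setting():
    # in the realistic 22-h cycle, the cycle mean divided into ln2/22 gives
    # the quoted division rate 0.05541
    params = PDEParams.from_ratio(1 / 16, 1 / 28, 10**-0.605)
    pi2 = mean_g2_closed_form(params)
    assert (math.log(2) / 22) / pi2 == pytest.approx(0.05541, rel=5e-4)


def test_mean_g2_independent_of_p0():
    a = PDEParams(v=1 / 16, u=1 / 28, p0=1.0, q0=0.3)
    b = PDEParams(v=1 / 16, u=1 / 28, p0=5.0, q0=1.5)
    assert mean_g2_closed_form(a) == pytest.approx(mean_g2_closed_form(b), rel=1e-12)


def test_mean_g2_stable_at_extreme_ratios():
    for ls in (-9.5, -6.0, 6.0, 9.5):
        val = mean_g2_closed_form(PDEParams.from_ratio(1 / 16, 1 / 28, 10.0**ls))
        assert 0.0 < val < 1.0
    # symmetric case stays in bounds
    assert 0 < mean_g2_closed_form(PDEParams.from_ratio(1 / 20, 1 / 20, 1.0)) < 1


@pytest.mark.parametrize(
    "log10_s,expected_t_extreme",
    [(-0.605, ("max", 14.0)), (2.645, ("min", 8.0))],
)
def test_oscillation_extrema_times_and_grid_agreement(log10_s, expected_t_extreme):
    params = PDEParams.from_ratio(1 / 16, 1 / 28, 10.0**log10_s)
    summary = oscillation_extrema(params)
    kind, t_exp = expected_t_extreme
    assert (summary.t_max if kind == "max" else summary.t_min) == t_exp
    # dense-grid oracle
    grid = np.linspace(0.0, params.schedule.eta1, 22001)
    pi2 = g2_proportion(params, grid)
    assert summary.pi2_max == pytest.approx(pi2.max(), abs=1e-6)
    assert summary.pi2_min == pytest.approx(pi2.min(), abs=1e-6)
    assert summary.amplitude == pytest.approx(pi2.max() - pi2.min(), abs=1e-6)


def test_log_population_safe_for_many_cycles():
    params = PDEParams.from_ratio(1 / 16, 1 / 28, 1.0)
    t = 22.0 * 5000  # 5000 doublings: N itself would overflow
    logN = log_total_population(params, t)
    assert np.isfinite(logN)
    assert logN == pytest.approx(5000 * math.log(2) + math.log(total_population(params, 0.0)))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(pde_triples, st.floats(0.0, 80.0))
def test_periodicity_and_doubling(triple, t):
    v, u, ls = triple
    params = PDEParams.from_ratio(v, u, 10.0**ls)
    eta1 = params.schedule.eta1
    assert g2_proportion(params, t + eta1) == pytest.approx(
        g2_proportion(params, t), rel=1e-9, abs=1e-12
    )
    assert total_population(params, t + eta1) == pytest.approx(
        2.0 * total_population(params, t), rel=1e-9
    )


def test_model_wrapper_and_timeseries(realistic_params):
    model = CellCyclePDE(realistic_params)
    df = model.timeseries([0.0, 11.0, 22.0])
    assert list(df.columns) == ["t", "N", "pi2"]
    assert df["N"].iloc[2] == pytest.approx(2 * df["N"].iloc[0])
    assert model.mean_g2("quadrature") == pytest.approx(model.mean_g2(), abs=1e-8)
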