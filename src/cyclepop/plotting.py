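"""Figure regeneration: the standard plots of the PDE/ODE comparison."""

from __future__ import annotations

import numpy as np

from .datasets import SamplingSchedule, sample_trajectory
from .fitting import FitConfig, ODETrajectoryModel
from .matching import match_forward
from .ode import ode_solve
from .pde import PDEParams, g2_proportion, log_total_population, oscillation_extrema, total_population

__all__ = ["FIGURES", "make_figure"]


def _ax(figsize=(6, 4)):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt.subplots(figsize=figsize)


def fig_density_profiles(path):
    """Density over phi at several times within one cycle (v=1/16, u=1/28,
    p0=1, q0=3)."""
    import matplotlib.pyplot as plt

    from .pde import density

    params = PDEParams(v=1 / 16, u=1 / 28, p0=1.0, q0=3.0)
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharey=True)
    for ax, t in zip(axes.ravel(), (0.0, 6.0, 12.0, 18.0)):
        prof = density(params, t)
        ax.stairs(prof.values, prof.breakpoints, fill=True, alpha=0.5)
        ax.set_title(f"t = {t:g} h")
        ax.set_xlabel(r"$\varphi$")
        ax.set_ylabel(r"$p(\varphi, t)$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def fig_g2_oscillations(path):
    """G2 proportion over five 22-h cycles for two initial ratios
    (v=1/28, u=1/16; s=10^-0.5 and 10^5), with cycle means."""
    fig, ax = _ax((7, 4))
    t = np.linspace(0, 110, 4001)
    for s, color in ((10**-0.5, "tab:blue"), (1e5, "tab:orange")):
        params = PDEParams.from_ratio(1 / 28, 1 / 16, s)
        ax.plot(t, g2_proportion(params, t), color=color, label=f"s = {s:g}")
        from .pde import mean_g2_closed_form

        ax.axhline(mean_g2_closed_form(params), color=color, ls="--", lw=1)
    ax.set_xlabel("t (h)")
    ax.set_ylabel(r"$\pi_2(t)$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    import matplotlib.pyplot as plt

    plt.close(fig)


def fig_growth_swap(path):
    """log N(t) for swapped velocity pairs with the same 15-h cycle, against
    exponential growth at the cycle-mean rate."""
    fig, ax = _ax((7, 4))
    t = np.linspace(0, 60, 2001)
    for v, u, color in ((0.04, 0.2, "tab:blue"), (0.2, 0.04, "tab:orange")):
        params = PDEParams.from_ratio(v, u, 1.0)
        ax.plot(t, log_total_population(params, t), color=color, label=f"(v,u)=({v},{u})")
    eta1 = 15.0
    ax.plot(t, np.log(2) / eta1 * t, "k--", lw=1, label="mean growth")
    ax.set_xlabel("t (h)")
    ax.set_ylabel("ln N(t)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    import matplotlib.pyplot as plt

    plt.close(fig)


def fig_rates_vs_s(path):
    """Matched rates k1, k2 as the initial ratio s varies (v=1/16, u=1/28)."""
    fig, ax = _ax((7, 4))
    ls = np.linspace(-5, 5, 801)
    k1 = np.empty_like(ls)
    k2 = np.empty_like(ls)
    for i, x in enumerate(ls):
        m = match_forward(1 / 16, 1 / 28, 10.0**x)
        k1[i], k2[i] = m.k1, m.k2
    ax.plot(ls, k1, label=r"$k_1$")
    ax.plot(ls, k2, label=r"$k_2$")
    ax.set_xlabel(r"$\log_{10} s$")
    ax.set_ylabel("matched rate (/h)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    import matplotlib.pyplot as plt

    plt.close(fig)


def fig_pde_vs_matched_ode(path):
    """PDE trajectories vs the matched ODE for the two-root pair
    s = 10^-0.605 and 10^2.645 (v=1/16, u=1/28)."""
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4))
    t = np.linspace(0, 120, 4001)
    for s, color in ((10**-0.605, "tab:blue"), (10**2.645, "tab:orange")):
        params = PDEParams.from_ratio(1 / 16, 1 / 28, s)
        m = match_forward(1 / 16, 1 / 28, s)
        init = (1.0 / (1 + s), s / (1 + s))
        sol = ode_solve((m.k1, m.k2), init, t)
        ax1.plot(t, g2_proportion(params, t), color=color, lw=1, label=f"PDE, s=10^{np.log10(s):.3f}")
        ax1.plot(t, sol["g2"], color=color, ls="--", lw=1)
        ax2.plot(t, log_total_population(params, t), color=color, lw=1)
        ax2.plot(t, np.log(sol["N"]), color=color, ls="--", lw=1)
    ax2.plot(t, np.log(2) / 22 * t, "k:", lw=1, label="mean growth")
    ax1.set_xlabel("t (h)")
    ax1.set_ylabel(r"$\pi_2$ / $g_2$")
    ax1.legend(fontsize=8)
    ax2.set_xlabel("t (h)")
    ax2.set_ylabel("ln N")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _amplitude_grid(L1_vals, L2_vals, s_vals):
    A = np.empty((len(s_vals), len(L1_vals)))
    for i, s in enumerate(s_vals):
        for j, L1 in enumerate(L1_vals):
            params = PDEParams.from_ratio(1 / (2 * L1), 1 / (2 * L2_vals[j]), s)
            A[i, j] = oscillation_extrema(params).amplitude
    return A


def fig_amplitude_heatmap(path, n=61):
    """Oscillation amplitude, matched rates and mean G2 proportion over
    (G1 length, log10 s) at a fixed 22-h cycle."""
    import matplotlib.pyplot as plt

    L1_vals = np.linspace(1.0, 21.0, n)
    ls_vals = np.linspace(-5, 5, n)
    A = np.empty((n, n))
    K1 = np.empty((n, n))
    K2 = np.empty((n, n))
    P = np.empty((n, n))
    for i, lsv in enumerate(ls_vals):
        s = 10.0**lsv
        for j, L1 in enumerate(L1_vals):
            L2 = 22.0 - L1
            v, u = 1 / (2 * L1), 1 / (2 * L2)
            params = PDEParams.from_ratio(v, u, s)
            A[i, j] = oscillation_extrema(params).amplitude
            m = match_forward(v, u, s)
            K1[i, j], K2[i, j], P[i, j] = m.k1, m.k2, m.mean_pi2
    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    for ax, Z, title in zip(
        axes.ravel(), (A, K1, K2, P), ("amplitude A", r"$k_1$", r"$k_2$", r"$\bar\pi_2$")
    ):
        im = ax.pcolormesh(L1_vals, ls_vals, Z, shading="auto")
        fig.colorbar(im, ax=ax)
        ax.set_xlabel(r"$L_1$ (h)")
        ax.set_ylabel(r"$\log_{10} s$")
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def fig_amplitude_vs_lengths(path, n=41):
    """Amplitude over (L1, L2) for s = 10, 1, 0.1."""
    import matplotlib.pyplot as plt

    L = np.linspace(1.0, 22.0, n)
    fig, axes = plt.subplots(1, 3, figsize=(13, 4), sharey=True)
    for ax, s in zip(axes, (10.0, 1.0, 0.1)):
        A = np.empty((n, n))
        for i, L2 in enumerate(L):
            for j, L1 in enumerate(L):
                params = PDEParams.from_ratio(1 / (2 * L1), 1 / (2 * L2), s)
                A[i, j] = oscillation_extrema(params).amplitude
        im = ax.pcolormesh(L, L, A, shading="auto", vmin=0, vmax=1)
        ax.set_xlabel(r"$L_1$ (h)")
        ax.set_title(f"s = {s:g}")
    axes[0].set_ylabel(r"$L_2$ (h)")
    fig.colorbar(im, ax=axes, shrink=0.85)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def fig_fit_comparison(path, seed=0):
    """Fits to PDE samples at 7/22/30-h intervals vs the matched ODE
    (v=1/16, u=1/28, s=10^3)."""
    import matplotlib.pyplot as plt

    v, u, s = 1 / 16, 1 / 28, 1e3
    params = PDEParams.from_ratio(v, u, s)
    m = match_forward(v, u, s)
    init = (1.0 / (1 + s), s / (1 + s))
    t = np.linspace(0, 120, 2401)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4))
    ax1.plot(t, np.log(total_population(params, t)), color="0.6", lw=1, label="PDE")
    ax2.plot(t, g2_proportion(params, t), color="0.6", lw=1)
    solm = ode_solve((m.k1, m.k2), init, t)
    ax1.plot(t, np.log(solm["N"]), "b-", lw=1.2, label="matched ODE")
    ax2.plot(t, solm["g2"], "b-", lw=1.2)
    for interval, color in ((7.0, "purple"), (22.0, "green"), (30.0, "hotpink")):
        data = sample_trajectory(params, SamplingSchedule(interval=interval, horizon=120.0))
        res = ODETrajectoryModel(data, FitConfig(seed=seed)).fit()
        sol = ode_solve(res.params, init, t)
        ax1.plot(t, np.log(sol["N"]), ls="--", color=color, lw=1, label=f"fit, {interval:g} h")
        ax2.plot(t, sol["g2"], ls="--", color=color, lw=1)
        ax1.plot(data.t, np.log(data.N), "o", color=color, ms=3)
        ax2.plot(data.t, data.pi2, "o", color=color, ms=3)
    ax1.set_xlabel("t (h)")
    ax1.set_ylabel("ln N")
    ax1.legend(fontsize=8)
    ax2.set_xlabel("t (h)")
    ax2.set_ylabel(r"$\pi_2$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


FIGURES = {
    "fig2": fig_density_profiles,
    "fig3": fig_g2_oscillations,
    "fig4": fig_growth_swap,
    "fig8": fig_rates_vs_s,
    "fig9": fig_pde_vs_matched_ode,
    "fig10": fig_amplitude_heatmap,
    "fig11": fig_amplitude_vs_lengths,
    "fig12": fig_fit_comparison,
}


def make_figure(name: str, path) -> None:
    if name not in FIGURES:
        raise ValueError(f"unknown figure {name!r}; choose from {sorted(FIGURES)}")
    FIGURES[name](path)
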