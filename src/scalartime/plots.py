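"""Diagnostic figure panels for timing experiments (matplotlib, optional)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .experiments import ExperimentResult

__all__ = ["plot_experiment"]


def plot_experiment(result: ExperimentResult, path: str | Path) -> Path:
    """Three-panel summary: mean vs target, std vs mean, rescaled CDFs."""
    tab = result.per_target
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))

    ax = axes[0]
    ax.plot(tab["t_tar"], tab["mean_test"], "o", label="simulation")
    ax.plot(tab["t_tar"], tab["discrete_mean"], "s", mfc="none", label="discrete")
    lims = [0, tab["t_tar"].max() * 1.1]
    ax.plot(lims, lims, "k--", lw=0.8)
    ax.set_xlabel("target time (s)")
    ax.set_ylabel(r"mean $t_{est}$ (s)")
    ax.legend(frameon=False)

    ax = axes[1]
    ax.plot(tab["mean_test"], tab["std_test"], "o", label="simulation")
    ax.plot(tab["discrete_mean"], tab["discrete_std"], "s", mfc="none", label="discrete")
    f = result.scalar_fit_sim
    xs = np.linspace(0, tab["mean_test"].max() * 1.1, 50)
    ax.plot(xs, f.slope * xs + f.intercept, "k-", lw=0.8,
            label=f"fit: slope={f.slope:.3f}, $R^2$={f.r_squared:.3f}")
    ax.set_xlabel(r"mean $t_{est}$ (s)")
    ax.set_ylabel(r"$\sigma_T$ (s)")
    ax.legend(frameon=False, fontsize=8)

    ax = axes[2]
    for t_tar, grp in result.trials.groupby("t_tar"):
        x = np.sort(grp["t_est"] / grp["t_est"].mean())
        ax.step(x, np.arange(1, x.size + 1) / x.size, label=f"{t_tar:.2g} s")
    ax.set_xlabel(r"$t_{est}/\langle t_{est}\rangle$")
    ax.set_ylabel("CDF")
    ax.legend(frameon=False, fontsize=7)

    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
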