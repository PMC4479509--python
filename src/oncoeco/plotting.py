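"""Optional matplotlib figure export (kept out of the computational core).

Importing this module requires matplotlib; nothing else in the package
depends on it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .simulate import Trajectory
from .sweep import SweepGrid

__all__ = ["plot_heatmap", "plot_scenarios"]


def plot_heatmap(grid: SweepGrid, path: str | Path, *, dpi: int = 150):
    """Equilibrium-fraction surface, black (0) to white (1); non-converged
    cells are hatched in red."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    masked = np.ma.masked_where(~grid.converged, grid.fraction)
    cmap = plt.get_cmap("gray").copy()
    cmap.set_bad("red")
    im = ax.pcolormesh(
        grid.sigma_values, grid.theta_values, masked, cmap=cmap, vmin=0.0, vmax=1.0, shading="nearest"
    )
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"resource supply $\sigma$ (resource-units/year)")
    ax.set_ylabel(r"immune elimination $\theta$ (1/year)")
    ax.set_title("Equilibrium cancer fraction")
    fig.colorbar(im, ax=ax, label="C / (H + C)")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return Path(path)


def plot_scenarios(
    trajectories: list[Trajectory], labels: list[str], path: str | Path, *, dpi: int = 150
):
    """One row per scenario: disturbance profiles (left), cancer dynamics
    (right)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(trajectories)
    fig, axes = plt.subplots(n, 2, figsize=(9, 2.0 * n), sharex=True, squeeze=False)
    for i, (traj, label) in enumerate(zip(trajectories, labels)):
        left, right = axes[i]
        left.plot(traj.times, traj.theta_eff, drawstyle="steps-post", label=r"$\theta$")
        ax2 = left.twinx()
        ax2.plot(
            traj.times, traj.sigma_eff, drawstyle="steps-post", color="tab:orange", label=r"$\sigma$"
        )
        left.set_ylabel(r"$\theta_{\rm eff}$")
        ax2.set_ylabel(r"$\sigma_{\rm eff}$")
        right.plot(traj.times, traj.fractions, color="tab:red")
        right.set_ylabel("C/(H+C)")
        right.set_ylim(0, 1)
        right.set_title(label, fontsize=9)
    axes[-1][0].set_xlabel("time (years)")
    axes[-1][1].set_xlabel("time (years)")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return Path(path)
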