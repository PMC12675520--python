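"""Figure helpers for the posterior analyses.

Each function draws on a provided (or fresh) matplotlib Axes and returns
it, so figures compose; nothing is written to disk unless the caller
saves the figure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "plot_coupling_factors",
    "plot_occupancy_trajectory",
    "plot_variance_components",
    "plot_predictive_bands",
]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_coupling_factors(samples: pd.DataFrame, ax=None):
    """Log-log scatter of on-rate vs off-rate coupling factors.

    The diagonal is pure equilibrium shift (regular allosterism); points
    far up the diagonal's perpendicular are catalytic (both rates up) or
    inhibitory (both down)."""
    ax = _axes(ax)
    pairs = [("RB_bon", "RB", "A-side binding"), ("BR_bon", "BR", "B-side binding"),
             ("RB_ron", "RB", "A-side rotation"), ("BR_ron", "BR", "B-side rotation")]
    for on_col, eq_col, label in pairs:
        if on_col not in samples.columns:
            continue
        on = samples[on_col].to_numpy()
        off = on / samples[eq_col].to_numpy()
        ax.scatter(on, off, s=4, alpha=0.3, label=label)
    lims = ax.get_xlim()
    grid = np.geomspace(max(lims[0], 1e-3), lims[1], 10)
    ax.plot(grid, grid, "k--", lw=0.8)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("on-rate coupling factor")
    ax.set_ylabel("off-rate coupling factor")
    ax.legend(fontsize=7)
    return ax


def plot_occupancy_trajectory(occ, by_class: bool = True, classes=None, ax=None):
    """State (or rotational-class) probabilities over time."""
    ax = _axes(ax)
    P = occ.probabilities
    if by_class and classes is not None:
        classes = np.asarray(classes)
        for n in sorted(set(classes.tolist())):
            ax.plot(occ.times, P[:, classes == n].sum(axis=1), label=f"{n} rotated")
    else:
        for j, lab in enumerate(occ.state_labels):
            ax.plot(occ.times, P[:, j], label=lab)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("probability")
    ax.legend(fontsize=7)
    return ax


def plot_variance_components(vp: pd.DataFrame, ax=None):
    """Stacked per-interval gating / white / pink variance contributions."""
    ax = _axes(ax)
    t = vp["t0_s"].to_numpy()
    ax.fill_between(t, 0, vp["gating_var"], step="post", label="gating")
    ax.fill_between(t, vp["gating_var"], vp["gating_var"] + vp["white_var"],
                    step="post", label="white")
    ax.fill_between(t, vp["gating_var"] + vp["white_var"], vp["total_var"],
                    step="post", label="pink")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("variance (pA$^2$)")
    ax.set_yscale("log")
    ax.legend(fontsize=7)
    return ax


def plot_predictive_bands(bands: pd.DataFrame, observed=None, ax=None):
    """Posterior predictive quantile bands, optionally over the data."""
    ax = _axes(ax)
    t = bands["time_s"].to_numpy()
    ax.fill_between(t, bands["q05"], bands["q95"], alpha=0.3, label="90% band")
    ax.plot(t, bands["median"], lw=0.8, label="median")
    if observed is not None:
        t_obs, y_obs = observed
        ax.plot(t_obs, y_obs, "k", lw=0.5, alpha=0.7, label="observed")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("current (pA)")
    ax.legend(fontsize=7)
    return ax
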