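"""Plot helpers: V_A densities and average-effect trajectories."""

from __future__ import annotations

import numpy as np


def plot_va_density(summaries, ax=None, quantity="va"):
    """Overlaid density histograms of per-set variance values.

    ``summaries`` is an iterable of EnsembleVarianceSummary; one translucent
    histogram per summary, labelled by its epistasis/correction flags.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for s in summaries:
        label = ("epistasis" if s.epistasis_included else "no epistasis") + (
            ", corrected" if s.corrected else ", uncorrected"
        )
        ax.hist(s.values[quantity], bins=30, density=True, alpha=0.5, label=label)
    ax.set_xlabel(f"{quantity.upper()} (trait units²)")
    ax.set_ylabel("density")
    ax.legend()
    return ax


def plot_alpha_trajectory(traj, ax=None):
    """Scatter of α vs donor-allele frequency with trend and baseline lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(traj.points["p"], traj.points["alpha"], s=12, alpha=0.6)
    grid = np.linspace(0, 1, 50)
    ax.plot(grid, traj.intercept + traj.slope * grid, "--", label="with epistasis (fit)")
    ax.plot(grid, traj.baseline(grid), "k-", label="no epistasis")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel(f"donor-allele frequency at {traj.locus}")
    ax.set_ylabel("average effect α")
    ax.set_title(f"{traj.trait} — {traj.locus}")
    ax.legend()
    return ax
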