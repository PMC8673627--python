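"""Assembly-trajectory figures: populations, ribosome fractions,
metabolites and entropy production on one log-time axis."""

from __future__ import annotations

import numpy as np

from .assembly import group_abundance_series


def plot_assembly(trajectory, community=None, *, save=None):
    """Four-panel overview of one assembly run.

    Populations (log), ribosome fractions, metabolite amounts (linear) and
    the community entropy-production rate, all against log time.  Returns
    the matplotlib figure; ``save`` writes it (e.g. to SVG).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(4, 1, figsize=(7, 10), sharex=True)
    t = np.maximum(trajectory.t, 1.0)

    ax = axes[0]
    N = np.maximum(trajectory.N, 1e-2)
    ax.plot(t, N, lw=0.8)
    ax.set_yscale("log")
    ax.set_ylabel("abundance (cells)")

    ax = axes[1]
    ax.plot(t, trajectory.phi_R, lw=0.8)
    ax.set_ylabel(r"ribosome fraction $\phi_R$")

    ax = axes[2]
    ax.plot(t, trajectory.C, lw=1.0)
    ax.set_ylabel("metabolite amount (mol)")

    ax = axes[3]
    ax.plot(t, trajectory.sigma, lw=1.0, color="k")
    ax.set_ylabel(r"$\sigma$ (J K$^{-1}$ s$^{-1}$)")
    ax.set_xlabel("time (s)")
    ax.set_xscale("log")

    fig.tight_layout()
    if save is not None:
        fig.savefig(save)
    return fig


def plot_group_abundances(trajectory, community, *, save=None):
    """Relative functional-group abundances over time."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ab = group_abundance_series(trajectory, community)
    fig, ax = plt.subplots(figsize=(7, 4))
    t = np.maximum(trajectory.t, 1.0)
    ax.stackplot(t, [ab[c].fillna(0.0) for c in ab.columns],
                 labels=list(ab.columns))
    ax.set_xscale("log")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("relative abundance")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    if save is not None:
        fig.savefig(save)
    return fig
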