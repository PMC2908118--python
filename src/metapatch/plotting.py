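"""Simple diagnostic figures."""

from __future__ import annotations

import numpy as np


def plot_run(run, ax=None):
    """Host (solid) and parasitoid (dotted) trajectories, one line per patch."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = np.arange(1, run.n_steps + 1)
    for i in range(run.H.shape[1]):
        ax.plot(t, run.H[:, i], lw=0.8, label=f"host patch {i}")
        ax.plot(t, run.P[:, i], lw=0.8, ls=":", label=f"parasitoid patch {i}")
    ax.axvline(run.burn_in, color="grey", lw=0.5)
    ax.set_xlabel("time step")
    ax.set_ylabel("abundance")
    ax.legend(fontsize="x-small")
    return ax


def plot_correlation_surface(surface_df, ax=None):
    """Heatmap of mean between-patch host correlation over the dispersal grid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pivot = surface_df.pivot(index="dP", columns="dH", values="mean_correlation")
    im = ax.pcolormesh(pivot.columns, pivot.index, pivot.to_numpy(),
                       cmap="RdBu_r", vmin=-1, vmax=1, shading="nearest")
    ax.set_xlabel("host dispersal proportion")
    ax.set_ylabel("parasitoid dispersal proportion")
    ax.figure.colorbar(im, ax=ax, label="mean host correlation")
    return ax
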