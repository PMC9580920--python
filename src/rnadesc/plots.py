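"""Optional matplotlib views of a dataset summary.

matplotlib is imported lazily so the core library works without it.
Each function takes an axes (or creates one) and returns it.
"""

from __future__ import annotations

import numpy as np


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_rg_vs_length(summary, ax=None):
    """Rg–L scatter with the fitted power law(s) overlaid."""
    ax = _ax(ax)
    t = summary.table
    ax.loglog(t["L"], t["rg"], "o", ms=4, alpha=0.6, label="structures")
    grid = np.geomspace(t["L"].min(), t["L"].max(), 50)
    if summary.power_law:
        a, b = summary.power_law
        ax.loglog(grid, a * grid ** b, "-", label=f"{a:.2f}·L^{b:.2f}")
    if summary.power_law_short:
        a, b = summary.power_law_short
        short = grid[grid < 100]
        if short.size:
            ax.loglog(short, a * short ** b, "--", label=f"{a:.2f}·L^{b:.2f} (L<100)")
    ax.set_xlabel("length L (nt)")
    ax.set_ylabel("Rg (Å)")
    ax.legend()
    return ax


def plot_shape_distributions(summary, ax=None):
    """Histograms of asphericity Δ and shape parameter S."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, axes = plt.subplots(1, 2, figsize=(8, 3))
    else:
        axes = ax
    axes[0].hist(summary.table["asphericity"], bins=20, range=(0, 1))
    axes[0].set_xlabel("asphericity Δ")
    axes[1].hist(summary.table["shape"], bins=20, range=(-0.25, 2.0))
    axes[1].set_xlabel("shape parameter S")
    return axes


def plot_motif_histogram(counter, kind: str = "", ax=None):
    """Bar chart of a motif length histogram (stem, hairpin, …)."""
    ax = _ax(ax)
    if counter:
        lengths = sorted(counter)
        ax.bar(lengths, [counter[l] for l in lengths])
    ax.set_xlabel(f"{kind} length")
    ax.set_ylabel("count")
    return ax


def plot_rho_theta(records, ax=None):
    """Polar ρ–θ scatter of pair/stack geometry records (CylCoord list)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta = np.radians([c.theta for c in records])
    rho = [c.rho for c in records]
    ax.plot(theta, rho, ".", ms=3, alpha=0.5)
    for boundary in (60, 180, 300):
        ax.plot([np.radians(boundary)] * 2, [0, max(rho, default=1)],
                ":", color="grey", lw=1)
    return ax
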