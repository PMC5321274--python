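"""Minimal figure helpers: Ks/age histograms with mixture overlays and
omega-through-time bar charts."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from scipy.stats import norm  # noqa: E402

_COMPONENT_COLORS = ["red", "gold", "tab:blue", "green", "purple"]


def plot_distribution_with_fit(values, fit=None, path=None, xlabel="Ks", bins=60):
    """Histogram of a Ks or age sample with fitted normal components."""
    values = np.asarray(list(values), dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(values, bins=bins, density=True, color="0.8", edgecolor="0.6")
    if fit is not None:
        grid = np.linspace(values.min(), values.max(), 400)
        for i, c in enumerate(sorted(fit.components, key=lambda c: c.mean)):
            dens = c.proportion * norm.pdf(grid, c.mean, c.sd)
            color = _COMPONENT_COLORS[i % len(_COMPONENT_COLORS)]
            ax.plot(grid, dens, color=color, lw=1.5)
            ax.axvline(c.mean, color=color, ls="--", lw=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("density")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_omega_bins(bins, wgd_age=None, path=None):
    """Bar chart of mean omega per age bin (oldest on the left)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    centers = [(b.start + b.end) / 2 for b in bins]
    heights = [b.mean_omega if b.n_pairs else 0.0 for b in bins]
    ax.bar(centers, heights, width=0.9 * (bins[0].end - bins[0].start), color="0.6")
    if wgd_age is not None:
        ax.axvline(wgd_age, color="tab:blue", lw=1.5)
    ax.set_xlabel("age (myr)")
    ax.set_ylabel("mean Ka/Ks")
    ax.invert_xaxis()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
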