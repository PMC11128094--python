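"""Publication-style figures: tube overlays and marginal histograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .data_io import TimeSeriesDataset
from .ensemble import CredibleTube

__all__ = ["plot_tubes", "plot_marginals"]


def plot_tubes(
    tubes: dict[str, CredibleTube],
    path: str | Path,
    data: dict[str, TimeSeriesDataset] | None = None,
    ylabel: str = "observable",
) -> Path:
    """Overlay the median curves and credible tubes of several conditions."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    cmap = plt.get_cmap("tab10")
    for i, (cond, tube) in enumerate(tubes.items()):
        color = cmap(i % 10)
        ax.fill_between(tube.grid, tube.lower, tube.upper, alpha=0.25, color=color)
        ax.plot(tube.grid, tube.median, color=color, label=cond)
        if data and cond in data:
            ds = data[cond]
            ax.plot(ds.times, ds.values, "o", ms=3, alpha=0.5, color=color)
    ax.set_xlabel("time")
    ax.set_ylabel(ylabel)
    level = next(iter(tubes.values())).level
    ax.set_title(f"median and {level * 100:.0f}% credible tubes")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_marginals(
    marginals: dict[str, "np.ndarray | object"],
    hdis: dict[str, tuple[float, float]] | None,
    path: str | Path,
    parameter: str,
) -> Path:
    """Histogram of one parameter's marginal posterior per condition, with
    optional HDI bars underneath."""
    fig, ax = plt.subplots(figsize=(6, 4))
    cmap = plt.get_cmap("tab10")
    for i, (cond, draws) in enumerate(marginals.items()):
        draws = np.asarray(draws, dtype=float)
        color = cmap(i % 10)
        ax.hist(draws, bins=60, density=True, alpha=0.4, color=color, label=cond)
        if hdis and cond in hdis:
            lo, hi = hdis[cond]
            y = -0.03 * (i + 1) * ax.get_ylim()[1]
            ax.plot([lo, hi], [y, y], lw=3, color=color)
    ax.set_xlabel(parameter)
    ax.set_ylabel("posterior density")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
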