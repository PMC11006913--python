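"""Contrast and specificity scatter plots.

Both plot the per-k-mer contrast difference (variant minus reference)
against the reference affinity estimate; colors band the relevant
Q-value, and the specificity plot overlays the selected B-spline trend.
An optional highlight layer marks k-mers containing a query word on
either strand.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from ._util import revcomp

_BANDS = [(1e-6, "#b2182b"), (1e-3, "#ef8a62"), (0.05, "#fddbc7")]


def _scatter_by_q(ax, x, y, q):
    q = np.asarray(q, float)
    rest = np.ones(len(q), dtype=bool)
    for cut, color in _BANDS:
        sel = rest & (q < cut)
        ax.scatter(x[sel], y[sel], s=4, c=color, label=f"Q < {cut:g}", zorder=3)
        rest &= ~sel
    ax.scatter(x[rest], y[rest], s=3, c="#999999", alpha=0.5, label="n.s.", zorder=2)


def _highlight(ax, table, query):
    if not query:
        return
    rc = revcomp(query)
    sel = table["kmer"].str.contains(query) | table["kmer"].str.contains(rc)
    ax.scatter(
        table.loc[sel, "ref_estimate"], table.loc[sel, "contrast"],
        s=14, facecolors="none", edgecolors="#2166ac", linewidths=0.8,
        label=f"contains {query}", zorder=4,
    )


def contrast_plot(table, path, title: str = "", highlight: str | None = None):
    """Contrast difference vs reference affinity, colored by contrastQ bands."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    _scatter_by_q(ax, table["ref_estimate"].to_numpy(), table["contrast"].to_numpy(),
                  table["contrastQ"].to_numpy())
    _highlight(ax, table, highlight)
    ax.axhline(0, color="black", lw=0.6)
    ax.set_xlabel("reference affinity estimate (log2)")
    ax.set_ylabel("contrast (variant - reference, log2)")
    ax.set_title(title)
    ax.legend(fontsize=7, markerscale=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def specificity_plot(table, trend, path, title: str = "", highlight: str | None = None):
    """Same axes with the selected trendline, colored by specificityQ bands."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    x = table["ref_estimate"].to_numpy()
    _scatter_by_q(ax, x, table["contrast"].to_numpy(), table["specificityQ"].to_numpy())
    _highlight(ax, table, highlight)
    grid = np.linspace(np.nanmin(x), np.nanmax(x), 200)
    ax.plot(grid, trend.predict(grid), color="black", lw=1.2, label=f"trend ({trend.selected})")
    ax.set_xlabel("reference affinity estimate (log2)")
    ax.set_ylabel("contrast (variant - reference, log2)")
    ax.set_title(title)
    ax.legend(fontsize=7, markerscale=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
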