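"""Structure-style stacked-bar rendering of Q matrices."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless by default; callers can switch backends first
import matplotlib.pyplot as plt
import numpy as np

from .qmatrix import QMatrix

__all__ = ["plot_q", "plot_groups"]


def plot_q(
    q: QMatrix,
    ax: "plt.Axes | None" = None,
    sort_individuals: bool = False,
    colors: Sequence | None = None,
    title: str | None = None,
) -> "plt.Axes":
    """Draw one Q matrix as stacked bars, one bar per individual.

    Segment heights are the membership coefficients, so every bar has total
    height 1.  Segments are stacked in input column order — no automatic
    cluster alignment across matrices is attempted.  With
    ``sort_individuals`` the bars are ordered by dominant cluster and, within
    it, by decreasing membership in that cluster.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(max(3.0, q.n_individuals / 12), 2.4))
    v = q.values
    if sort_individuals:
        dominant = np.argmax(v, axis=1)
        order = np.lexsort((-v[np.arange(len(v)), dominant], dominant))
        v = v[order]
    if colors is None:
        cmap = plt.get_cmap("tab10" if q.n_clusters <= 10 else "tab20")
        colors = [cmap(k % cmap.N) for k in range(q.n_clusters)]
    x = np.arange(v.shape[0])
    bottom = np.zeros(v.shape[0])
    labels = q.col_labels or [f"cluster {k + 1}" for k in range(q.n_clusters)]
    for k in range(v.shape[1]):
        ax.bar(x, v[:, k], bottom=bottom, width=1.0, color=colors[k],
               label=labels[k], linewidth=0)
        bottom += v[:, k]
    ax.set_xlim(-0.5, v.shape[0] - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("membership")
    ax.set_xticks([])
    if title:
        ax.set_title(title, fontsize=9)
    return ax


def plot_groups(
    qs: Sequence[QMatrix],
    titles: Sequence[str] | None = None,
    sort_individuals: bool = False,
) -> "plt.Figure":
    """One stacked-bar panel per Q matrix, sharing the y axis."""
    n = len(qs)
    widths = [max(1.0, q.n_individuals) for q in qs]
    fig, axes = plt.subplots(
        1, n, figsize=(max(4.0, sum(widths) / 12), 2.6),
        gridspec_kw={"width_ratios": widths}, sharey=True, squeeze=False,
    )
    for j, (q, ax) in enumerate(zip(qs, axes[0])):
        t = titles[j] if titles else (q.group or f"group {j + 1}")
        plot_q(q, ax=ax, sort_individuals=sort_individuals, title=t)
        if j > 0:
            ax.set_ylabel("")
    fig.tight_layout()
    return fig
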