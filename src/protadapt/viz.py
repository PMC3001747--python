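"""The three signature plots: compositional deltas, substitution-bias
bubble grid, and ranked per-family slopes.

Every figure is drawn from a table the analysis modules also emit, so
no figure contains data absent from the text outputs.
"""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .alphabet import STATE_LABELS21


def plot_delta_composition(
    table: pd.DataFrame,
    alpha: float = 0.05,
    title: str = "Compositional change",
    path=None,
):
    """Bar chart of per-feature mean deltas with SD error bars.

    ``table`` is the composition-scan frame (feature, mean_delta, sd,
    p, q_BY).  Features significant at q_BY < alpha are drawn in a
    distinct colour and starred.
    """
    if table is None or len(table) == 0:
        raise ValueError("empty composition table")
    feats = table["feature"].tolist()
    x = np.arange(len(feats))
    sig = table["q_BY"].to_numpy() < alpha if "q_BY" in table else np.zeros(len(feats), bool)
    colors = ["#d62728" if s else "#1f77b4" for s in sig]
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(feats)), 4))
    ax.bar(x, table["mean_delta"], yerr=table["sd"], color=colors, capsize=2)
    for xi, s in zip(x, sig):
        if s:
            y = table["mean_delta"].iloc[xi]
            off = table["sd"].iloc[xi] + 0.002
            ax.annotate("*", (xi, y + np.sign(y or 1) * off), ha="center")
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xticks(x)
    ax.set_xticklabels(feats, rotation=0 if max(map(len, map(str, feats))) <= 2 else 45)
    ax.set_ylabel("mean composition delta")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig


def plot_substitution_bubbles(
    scan: pd.DataFrame,
    alpha: float = 0.05,
    title: str = "Substitution pairs",
    path=None,
):
    """21x21 grid of substitution-pair counts.

    Marker size and colour scale with the forward count; pairs
    significant at p < alpha are drawn as upward triangles when the
    forward direction is favoured and downward triangles when
    non-favoured, circles otherwise.  Replaced residue on the y axis,
    replacement on the x axis; '~' is the indel state.
    """
    if scan is None or len(scan) == 0:
        raise ValueError("empty substitution scan")
    labels = list(STATE_LABELS21)
    pos = {lab: i for i, lab in enumerate(labels)}
    fig, ax = plt.subplots(figsize=(8.5, 8))
    counts = scan["a"].to_numpy(dtype=float)
    cmax = counts.max() if counts.max() > 0 else 1.0
    cmap = plt.get_cmap("viridis")
    for marker, sel in (
        ("^", (scan["p"] < alpha) & (scan["direction"] == "favoured")),
        ("v", (scan["p"] < alpha) & (scan["direction"] == "non_favoured")),
        ("o", ~((scan["p"] < alpha) & scan["direction"].isin(["favoured", "non_favoured"]))),
    ):
        sub = scan[sel & (scan["a"] > 0)]
        if len(sub) == 0:
            continue
        ax.scatter(
            [pos[y] for y in sub["y"]],
            [pos[x] for x in sub["x"]],
            s=20 + 180 * sub["a"] / cmax,
            c=sub["a"],
            cmap=cmap,
            vmin=0,
            vmax=cmax,
            marker=marker,
            edgecolors="k",
            linewidths=0.3,
        )
    sm = plt.cm.ScalarMappable(cmap=cmap, norm=plt.Normalize(0, cmax))
    fig.colorbar(sm, ax=ax, label="substitution count")
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels)
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels)
    ax.set_xlabel("replacement (target group)")
    ax.set_ylabel("replaced (source group)")
    ax.invert_yaxis()
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig


def plot_ranked_slopes(
    slopes: Sequence[float],
    trend_p: Optional[float] = None,
    title: str = "Ranked family slopes",
    path=None,
):
    """Slope coefficients sorted ascending against their rank, with a
    zero reference line and the cumulative Mann-Kendall p annotated."""
    slopes = np.asarray(list(slopes), dtype=float)
    if slopes.size == 0:
        raise ValueError("no slopes to plot")
    order = np.sort(slopes)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.arange(1, len(order) + 1), order, "o", ms=4)
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xlabel("rank")
    ax.set_ylabel(r"slope $\beta_1$")
    ax.set_title(title)
    if trend_p is not None:
        ax.annotate(
            f"cumulative Mann-Kendall p = {trend_p:.2g}",
            xy=(0.03, 0.95),
            xycoords="axes fraction",
            va="top",
        )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
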