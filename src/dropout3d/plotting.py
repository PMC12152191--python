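"""Cosmetic plots: UpSet-style intersection bars and |T| vs U_gene.

Plotting is optional everywhere in the pipeline; these helpers render
to a Matplotlib figure (Agg-safe) and are kept deliberately simple.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["upset_plot", "t_vs_u_plot"]


def upset_plot(
    membership: pd.DataFrame,
    counts: pd.Series,
    path: str | Path | None = None,
):
    """UpSet-style plot: intersection-size bars over a membership dot matrix."""
    if counts.empty:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.text(0.5, 0.5, "no called genes", ha="center", va="center")
        ax.axis("off")
        if path:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return fig

    sets = list(membership.columns)
    patterns = counts.sort_values(ascending=False)
    n = len(patterns)
    fig, (ax_bar, ax_dot) = plt.subplots(
        2, 1, figsize=(max(4, 0.6 * n + 2), 4.5),
        gridspec_kw={"height_ratios": [2.2, 1]}, sharex=True,
    )
    xs = np.arange(n)
    ax_bar.bar(xs, patterns.to_numpy(), color="0.25")
    for x, v in zip(xs, patterns.to_numpy()):
        ax_bar.text(x, v, str(int(v)), ha="center", va="bottom", fontsize=8)
    ax_bar.set_ylabel("genes")
    ax_bar.spines[["top", "right"]].set_visible(False)

    for x, pattern in enumerate(patterns.index):
        flags = pattern if isinstance(pattern, tuple) else (pattern,)
        for y, on in enumerate(flags):
            ax_dot.scatter(
                x, y, s=60, color="0.15" if on else "0.85", zorder=3
            )
        on_ys = [y for y, on in enumerate(flags) if on]
        if len(on_ys) > 1:
            ax_dot.plot([x, x], [min(on_ys), max(on_ys)], color="0.15", lw=1.5)
    ax_dot.set_yticks(range(len(sets)), sets, fontsize=8)
    ax_dot.set_xticks([])
    ax_dot.set_ylim(-0.5, len(sets) - 0.5)
    ax_dot.invert_yaxis()
    for spine in ax_dot.spines.values():
        spine.set_visible(False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def t_vs_u_plot(
    gene_table: pd.DataFrame,
    path: str | Path | None = None,
    title: str | None = None,
):
    """Scatter of |T score| against gene effect size U_gene."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(
        gene_table["u_gene"],
        gene_table["t_score"].abs(),
        s=10, alpha=0.6, color="#2b6cb0", edgecolors="none",
    )
    ax.set_xlabel("U_gene (median control-normalized log2FE)")
    ax.set_ylabel("|T score|")
    if title:
        ax.set_title(title)
    ax.spines[["top", "right"]].set_visible(False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
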