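"""Optional rendering of plot-ready tables (matplotlib required).

The analysis emits tidy tables; these helpers render the two standard
views: cumulative 3'-end position plots (solid = actual termini, dotted =
genome-encoded) and a stacked-bar version of the tail-composition matrix.
"""

from __future__ import annotations

import pandas as pd

BASE_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "U": "#d62728"}


def plot_cumulative(cum_dist: pd.DataFrame, ax=None, label_prefix: str = ""):
    """Plot one gene's cumulative end distribution (both modes if present)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    styles = {"apparent": "-", "templated": ":"}
    for mode, grp in cum_dist.groupby("mode"):
        ax.step(
            grp["position"],
            grp["cumulative_pct"],
            styles.get(mode, "-"),
            where="post",
            label=f"{label_prefix}{mode}",
        )
    ax.axvline(0, color="0.7", lw=0.8)
    ax.set_xlabel("position relative to mature 3' end (nt)")
    ax.set_ylabel("cumulative % of transcripts")
    ax.set_ylim(0, 105)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_tail_matrix(tail_matrix: pd.DataFrame, ax=None):
    """Stacked bars of % transcripts carrying each base per tail position."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    bottom = None
    for base in tail_matrix.columns:
        vals = tail_matrix[base].to_numpy()
        ax.bar(
            tail_matrix.index,
            vals,
            bottom=bottom,
            color=BASE_COLORS.get(base, "0.5"),
            label=base,
        )
        bottom = vals if bottom is None else bottom + vals
    ax.set_xlabel("tail position (nt)")
    ax.set_ylabel("% of transcripts")
    ax.legend(frameon=False, fontsize=8)
    return ax
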