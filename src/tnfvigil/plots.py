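"""Plotting helpers: per-drug ROR forest plots and an UpSet-style view of
the shared/unique signal decomposition.  Purely presentational; all
numbers come from the stats and sets modules."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .sets import SignalSetSummary

__all__ = ["forest_plot", "upset_plot"]


def forest_plot(signals: pd.DataFrame, drug: str, k: int = 30, path: str | Path | None = None):
    """Top-k positive signals for one drug, ROR with 95% CI on a log axis."""
    sub = (
        signals[(signals["drug"] == drug) & (signals["stratum"] == "all") & signals["is_signal"]]
        .sort_values("ror", ascending=False)
        .head(k)
        .iloc[::-1]
    )
    fig, ax = plt.subplots(figsize=(7, max(2, 0.28 * len(sub) + 1)))
    y = np.arange(len(sub))
    ax.errorbar(
        sub["ror"], y,
        xerr=[sub["ror"] - sub["ror_lo"], sub["ror_hi"] - sub["ror"]],
        fmt="s", color="black", ecolor="gray", capsize=2, markersize=4,
    )
    ax.axvline(1.0, color="red", lw=0.8, ls="--")
    ax.set_xscale("log")
    ax.set_yticks(y)
    ax.set_yticklabels(sub["event"])
    ax.set_xlabel("ROR (95% CI)")
    ax.set_title(f"{drug}: top {len(sub)} signals by ROR")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def upset_plot(summary: SignalSetSummary, max_patterns: int = 20, path: str | Path | None = None):
    """Minimal UpSet-style rendering: pattern bar chart over a dot matrix."""
    patterns = list(summary.intersections.items())[:max_patterns]
    drugs = sorted(summary.per_drug)
    counts = [len(v) for _, v in patterns]

    fig, (ax_bar, ax_dot) = plt.subplots(
        2, 1, figsize=(max(4, 0.5 * len(patterns) + 2), 5),
        gridspec_kw={"height_ratios": [2, 1]}, sharex=True,
    )
    x = np.arange(len(patterns))
    ax_bar.bar(x, counts, color="black", width=0.6)
    for xi, ci in zip(x, counts):
        ax_bar.text(xi, ci, str(ci), ha="center", va="bottom", fontsize=8)
    ax_bar.set_ylabel("events in pattern")
    for j, d in enumerate(drugs):
        for i, (members, _) in enumerate(patterns):
            filled = d in members
            ax_dot.scatter(i, j, s=40, c="black" if filled else "lightgray")
    for i, (members, _) in enumerate(patterns):
        idx = [drugs.index(d) for d in members]
        if len(idx) > 1:
            ax_dot.plot([i, i], [min(idx), max(idx)], color="black", lw=1.2)
    ax_dot.set_yticks(range(len(drugs)))
    ax_dot.set_yticklabels(drugs)
    ax_dot.set_xticks(x)
    ax_dot.set_xticklabels([])
    ax_dot.invert_yaxis()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
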