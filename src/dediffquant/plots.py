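"""Convenience figures: quadrant scatter plots and enrichment bar charts.

Plots are outputs only; every statistical assertion in the pipeline runs on
the tables, never on a figure.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .stats import ThresholdRule

__all__ = ["quadrant_scatter", "nes_barplot"]

_GENOTYPE_COLORS = ("tab:blue", "tab:red", "tab:green", "tab:purple")


def quadrant_scatter(
    records: pd.DataFrame,
    rule_a: ThresholdRule,
    rule_b: ThresholdRule,
    path: str | Path,
) -> None:
    """Per-cell scatter of channel A (x, nuclear TF) vs channel B (y, marker)
    with dashed cutoff lines at each mean - 1 SD threshold."""
    col_a = f"{rule_a.channel}_{rule_a.compartment}_median"
    col_b = f"{rule_b.channel}_{rule_b.compartment}_median"
    fig, ax = plt.subplots(figsize=(5, 5))
    for color, (geno, sub) in zip(_GENOTYPE_COLORS, records.groupby("genotype", sort=True)):
        ax.scatter(sub[col_a], sub[col_b], s=8, alpha=0.5, label=str(geno), color=color)
    ax.axvline(rule_a.cutoff, ls="--", color="k", lw=1)
    ax.axhline(rule_b.cutoff, ls="--", color="k", lw=1)
    ax.set_xlabel(f"{rule_a.channel} ({rule_a.compartment}) median")
    ax.set_ylabel(f"{rule_b.channel} ({rule_b.compartment}) median")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def nes_barplot(enrichment: pd.DataFrame, path: str | Path, adjp_threshold: float = 0.05) -> None:
    """Horizontal NES bars sorted by NES; significant sets (adjP below the
    threshold) drawn solid black, the rest gray."""
    df = enrichment.dropna(subset=["nes"]).sort_values("nes")
    colors = ["black" if a < adjp_threshold else "lightgray" for a in df["adjp"]]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(df))))
    ax.barh(df.index.astype(str), df["nes"], color=colors)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("normalized enrichment score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
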