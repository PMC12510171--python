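"""Cosmetic violin/histogram figures for condition comparisons."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["violin_by_condition", "integral_histogram"]


def violin_by_condition(
    objects: pd.DataFrame,
    value: str = "mean",
    out: str | Path | None = None,
):
    """Violin plot of a per-object readout per condition, with quartiles."""
    conditions = list(objects["condition"].drop_duplicates())
    data = [objects.loc[objects["condition"] == c, value].dropna() for c in conditions]
    fig, ax = plt.subplots(figsize=(1.5 * len(conditions) + 2, 4))
    ax.violinplot(data, showextrema=False)
    for i, vals in enumerate(data, start=1):
        q = np.quantile(vals, [0.25, 0.5, 0.75])
        ax.scatter([i] * 3, q, marker="s", s=12, color="k", zorder=3)
    ax.set_xticks(range(1, len(conditions) + 1), conditions, rotation=30)
    ax.set_ylabel(value)
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=120)
        plt.close(fig)
    return fig


def integral_histogram(
    objects: pd.DataFrame,
    peaks: dict | None = None,
    out: str | Path | None = None,
):
    """Histogram of per-object integrals with optional G1/G2 peak markers."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, sub in objects.groupby("condition", sort=False):
        ax.hist(sub["integral"], bins=80, alpha=0.5, label=str(cond), density=True)
        if peaks and str(cond) in peaks:
            pk = peaks[str(cond)]
            for key, ls in (("g1_x", "-"), ("g2_x", "--")):
                if pk.get(key):
                    ax.axvline(pk[key], linestyle=ls, color="k", lw=0.8)
    ax.set_xlabel("integral fluorescence")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=120)
        plt.close(fig)
    return fig
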