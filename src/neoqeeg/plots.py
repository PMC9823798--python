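"""Trend and correlation figures in the bedside-monitor style."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def trend_plot(
    per_subject: pd.DataFrame,
    cohort_mean: pd.Series,
    title: str,
    ylabel: str,
    out_path: str | Path | None = None,
    ax=None,
):
    """Grey per-subject epoch trends with the red cohort mean overlaid.

    ``per_subject`` is the epoch x subject pivot from
    :func:`neoqeeg.trends.long_term_trend`; the x axis is minutes
    relative to drug administration when the pivot was drug-aligned.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.2))
    x_min = per_subject.index.to_numpy() / 60.0
    for col in per_subject.columns:
        ax.plot(x_min, per_subject[col], color="0.7", lw=0.6)
    ax.plot(x_min, cohort_mean.to_numpy(), color="crimson", lw=1.8, label="cohort mean")
    ax.axvline(0.0, color="k", ls="--", lw=0.8)
    ax.set_xlabel("time from drug administration (min)")
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def delta_scatter(
    scatter: pd.DataFrame,
    feature: str,
    derivation: str,
    out_path: str | Path | None = None,
    annotation: str = "",
    ax=None,
):
    """Baseline (x) vs delta (y) scatter for one planned comparison."""
    sel = scatter[(scatter["feature"] == feature) & (scatter["derivation"] == derivation)]
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(sel["baseline"], sel["delta"], s=28, color="tab:blue", edgecolor="k", lw=0.4)
    ax.axhline(0.0, color="0.5", lw=0.8, ls=":")
    unit = " (uV)" if feature == "rEEG" else ""
    ax.set_xlabel(f"baseline median {feature}{unit}")
    ax.set_ylabel(f"delta (post - baseline){unit}")
    ax.set_title(f"{feature} {derivation}" + (f"  {annotation}" if annotation else ""))
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
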