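"""Long-term and short-term analysis designs around the drug timestamp.

Long-term: the full recording (2 h before + 2 h after administration)
is tiled into 2.5-minute epochs, each summarised per subject, and the
per-epoch cohort mean is overlaid — the bedside trend view.

Short-term: because the exact administration time is uncertain at the
bedside, a 1-minute gap is excluded on each side of the timestamp; the
baseline window is the 12 minutes before the gap and the effect window
the 10 minutes after it. Each window is tiled into 2.5-minute epochs,
the per-side medians are taken, and the drug effect is summarised as
``delta = post_median - baseline_median`` per subject and derivation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import EPOCH_LENGTH


@dataclass
class ShortTermDesign:
    """Window geometry of the pre/post contrast (all in seconds)."""

    baseline_length: float = 720.0   # 12 min baseline
    post_length: float = 600.0       # 10 min effect window
    gap: float = 60.0                # excluded on each side of the timestamp
    epoch_length: float = EPOCH_LENGTH
    anchor: str = "start"            # epoch tiling anchor within each window

    def __post_init__(self) -> None:
        if min(self.baseline_length, self.post_length, self.gap, self.epoch_length) <= 0:
            raise ValueError("all design lengths must be positive")
        if self.baseline_length < self.epoch_length or self.post_length < self.epoch_length:
            raise ValueError("windows must contain at least one epoch")
        if self.anchor not in ("start", "end"):
            raise ValueError("anchor must be 'start' or 'end'")


@dataclass
class ShortTermResult:
    """Per-subject, per-feature, per-derivation pre/post summary."""

    subject_id: str
    feature: str
    derivation: str
    baseline_median: float
    post_median: float
    n_epochs_baseline: int
    n_epochs_post: int

    @property
    def delta(self) -> float:
        return self.post_median - self.baseline_median

    @property
    def missing(self) -> bool:
        return not (np.isfinite(self.baseline_median) and np.isfinite(self.post_median))


def short_term_windows(
    drug_time: float, design: ShortTermDesign | None = None
) -> tuple[tuple[float, float], tuple[float, float], np.ndarray, np.ndarray]:
    """Baseline/post intervals (half-open) and their complete-epoch grids.

    Epochs tile each window from its ``anchor`` end; only complete
    epochs are kept (e.g. 720 s / 150 s -> 4 epochs, remainder dropped).
    """
    design = design or ShortTermDesign()
    baseline = (drug_time - design.gap - design.baseline_length, drug_time - design.gap)
    post = (drug_time + design.gap, drug_time + design.gap + design.post_length)

    def grid(t0: float, t1: float) -> np.ndarray:
        n = int((t1 - t0) / design.epoch_length)
        if design.anchor == "start":
            return t0 + np.arange(n) * design.epoch_length
        return t1 - (np.arange(n, 0, -1)) * design.epoch_length

    return baseline, post, grid(*baseline), grid(*post)


def epoch_values(
    trend_times: np.ndarray,
    trend_values: np.ndarray,
    grid: np.ndarray,
    epoch_length: float,
    min_valid_fraction: float = 0.5,
    summary: str = "mean",
) -> np.ndarray:
    """Summarise an aligned feature series into the given epoch grid.

    ``trend_times/values`` are window-level values (e.g. 2-s rEEG
    windows, NaN where masked); each epoch is the mean of its valid
    windows, NaN when fewer than ``min_valid_fraction`` are valid.
    """
    trend_times = np.asarray(trend_times, float)
    trend_values = np.asarray(trend_values, float)
    out = np.full(grid.size, np.nan)
    for k, t0 in enumerate(grid):
        sel = (trend_times >= t0) & (trend_times < t0 + epoch_length)
        vals = trend_values[sel]
        if vals.size == 0:
            continue
        if np.isfinite(vals).sum() >= min_valid_fraction * vals.size:
            out[k] = np.nanmean(vals) if summary == "mean" else np.nanmedian(vals)
    return out


def short_term_result(
    subject_id: str,
    feature: str,
    derivation: str,
    baseline_epoch_values: np.ndarray,
    post_epoch_values: np.ndarray,
) -> ShortTermResult:
    """Median over valid epochs per side; delta = post - baseline."""
    b = np.asarray(baseline_epoch_values, float)
    p = np.asarray(post_epoch_values, float)
    nb, np_ = int(np.isfinite(b).sum()), int(np.isfinite(p).sum())
    bmed = float(np.nanmedian(b)) if nb else float("nan")
    pmed = float(np.nanmedian(p)) if np_ else float("nan")
    return ShortTermResult(subject_id, feature, derivation, bmed, pmed, nb, np_)


def results_to_frame(results: list[ShortTermResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "feature": r.feature,
                "derivation": r.derivation,
                "baseline_median": r.baseline_median,
                "post_median": r.post_median,
                "delta": r.delta,
                "n_epochs_baseline": r.n_epochs_baseline,
                "n_epochs_post": r.n_epochs_post,
            }
            for r in results
        ]
    )


def long_term_trend(epoch_table: pd.DataFrame, drug_times: dict[str, float] | None = None):
    """Per-subject and cohort-mean trends from a tidy per-epoch table.

    ``epoch_table`` has columns subject_id, feature, name, epoch_start,
    value (one row per subject x feature x derivation x epoch). When
    ``drug_times`` is given, epoch starts are re-expressed relative to
    each subject's drug time so the cohort aligns at t=0. Returns
    (per_subject pivot, cohort_mean) per feature/name combination as a
    dict keyed by (feature, name).
    """
    table = epoch_table.copy()
    if drug_times is not None:
        table["epoch_start"] = [
            t - drug_times[s] for s, t in zip(table["subject_id"], table["epoch_start"])
        ]
    out = {}
    for (feature, name), sub in table.groupby(["feature", "name"]):
        pivot = sub.pivot_table(
            index="epoch_start", columns="subject_id", values="value", aggfunc="mean",
            dropna=False,
        )
        cohort_mean = pivot.mean(axis=1, skipna=True)
        out[(feature, name)] = (pivot, cohort_mean)
    return out
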