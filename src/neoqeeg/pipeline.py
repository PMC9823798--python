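"""End-to-end orchestration: recordings -> masks -> features -> results.

One call chain covers the whole analysis: each recording is band-pass
filtered (0.2-35 Hz), every analysed derivation gets an artifact mask
on the shared 2-second grid, range-EEG and ASI are computed per
2.5-minute epoch, the short-term pre/post design is evaluated around
the drug timestamp, and the planned cohort statistics are run on the
per-subject summary table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohort_stats, features, preprocessing, trends
from .eeg_io import ALL_DERIVATIONS, EEGRecording, derive
from .features import ASI_PAIRS, ASIParams
from .preprocessing import ArtifactConfig, ArtifactMask
from .trends import ShortTermDesign, ShortTermResult

logger = logging.getLogger("neoqeeg")

DEFAULT_REEG_DERIVATIONS = ("P3-P4", "F3-F4", "F3", "F4", "P3", "P4")


@dataclass
class AnalysisConfig:
    band: tuple[float, float] = preprocessing.DEFAULT_BAND
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    design: ShortTermDesign = field(default_factory=ShortTermDesign)
    asi_params: ASIParams = field(default_factory=ASIParams)
    reeg_derivations: tuple[str, ...] = DEFAULT_REEG_DERIVATIONS
    asi_pairs: dict = field(default_factory=lambda: dict(ASI_PAIRS))


def prepare_derivations(
    rec: EEGRecording, cfg: AnalysisConfig, names: tuple[str, ...]
) -> tuple[dict[str, np.ndarray], dict[str, ArtifactMask]]:
    """Band-passed derivation signals plus their artifact masks."""
    signals: dict[str, np.ndarray] = {}
    masks: dict[str, ArtifactMask] = {}
    for name in names:
        sig = preprocessing.bandpass(derive(rec, name), rec.sampling_rate, *cfg.band)
        signals[name] = sig
        masks[name] = preprocessing.detect_artifacts(sig, rec.sampling_rate, cfg.artifact)
    return signals, masks


def _needed_derivations(cfg: AnalysisConfig) -> tuple[str, ...]:
    names = list(cfg.reeg_derivations)
    for a, b in cfg.asi_pairs.values():
        for d in (a, b):
            if d not in names:
                names.append(d)
    return tuple(names)


def short_term_analysis(
    rec: EEGRecording, cfg: AnalysisConfig | None = None
) -> tuple[list[ShortTermResult], list[str]]:
    """Pre/post drug summary for one recording.

    Returns the per-derivation results plus a log of exclusions
    (insufficient recording coverage, fully masked windows, ...).
    """
    cfg = cfg or AnalysisConfig()
    d = cfg.design
    exclusions: list[str] = []
    t_lo = rec.drug_time - d.gap - d.baseline_length
    t_hi = rec.drug_time + d.gap + d.post_length
    if t_lo < 0 or t_hi > rec.duration:
        msg = (
            f"{rec.subject_id}: recording [0, {rec.duration:.0f}) s does not cover the "
            f"short-term design [{t_lo:.0f}, {t_hi:.0f}) s"
        )
        logger.warning(msg)
        return [], [msg]

    baseline, post, grid_b, grid_p = trends.short_term_windows(rec.drug_time, d)
    signals, masks = prepare_derivations(rec, cfg, _needed_derivations(cfg))
    results: list[ShortTermResult] = []

    for name in cfg.reeg_derivations:
        trend = features.reeg(signals[name], rec.sampling_rate, mask=masks[name], name=name)
        vb = trends.epoch_values(trend.times, trend.values, grid_b, d.epoch_length)
        vp = trends.epoch_values(trend.times, trend.values, grid_p, d.epoch_length)
        res = trends.short_term_result(rec.subject_id, "rEEG", name, vb, vp)
        if res.missing:
            exclusions.append(f"{rec.subject_id}: rEEG {name} missing (masked windows)")
        results.append(res)

    rng = np.random.default_rng(cfg.asi_params.rng_seed)
    for pair_name, (da, db) in cfg.asi_pairs.items():
        joint = masks[da].valid & masks[db].valid

        def pair_epochs(grid: np.ndarray) -> np.ndarray:
            return np.array(
                [
                    features.asi(
                        signals[da], signals[db], rec.sampling_rate, valid=joint,
                        params=cfg.asi_params, segment=(t0, t0 + d.epoch_length), rng=rng,
                    )
                    for t0 in grid
                ]
            )

        vb, vp = pair_epochs(grid_b), pair_epochs(grid_p)
        res = trends.short_term_result(rec.subject_id, "ASI", pair_name, vb, vp)
        if res.missing:
            exclusions.append(f"{rec.subject_id}: ASI {pair_name} missing (masked epochs)")
        results.append(res)
    return results, exclusions


def long_term_epoch_table(rec: EEGRecording, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Tidy 2.5-minute epoch features over the whole recording."""
    cfg = cfg or AnalysisConfig()
    signals, masks = prepare_derivations(rec, cfg, _needed_derivations(cfg))
    return features.feature_over_epochs(
        rec, masks,
        derivations=cfg.reeg_derivations,
        asi_pairs=cfg.asi_pairs,
        asi_params=cfg.asi_params,
        signals=signals,
    )


def cohort_short_term_table(
    recordings, cfg: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Short-term results for an iterable of recordings, as one tidy table."""
    cfg = cfg or AnalysisConfig()
    all_results: list[ShortTermResult] = []
    all_exclusions: list[str] = []
    for rec in recordings:
        res, excl = short_term_analysis(rec, cfg)
        all_results.extend(res)
        all_exclusions.extend(excl)
    return trends.results_to_frame(all_results), all_exclusions


def run_cohort_analysis(
    recordings,
    clinical_table: pd.DataFrame | None = None,
    cfg: AnalysisConfig | None = None,
    plan: cohort_stats.ComparisonPlan | None = None,
    rng_seed: int = 0,
):
    """Recordings + covariates -> (short-term table, stats, scatter, exclusions)."""
    cfg = cfg or AnalysisConfig()
    table, exclusions = cohort_short_term_table(recordings, cfg)
    stats, scatter = cohort_stats.run_planned_analyses(
        table, clinical_table, plan, rng_seed=rng_seed
    )
    return table, stats, scatter, exclusions
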