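"""Validation experiments run at the study's conditions.

Each function regenerates its own synthetic inputs from a seed, runs
the package's analysis path, and measures a property a correct
implementation must satisfy: oracle equivalence for range-EEG, null
calibration and synchrony-monotonicity for ASI, detector performance
on injected artifacts, window bookkeeping, end-to-end recovery of the
baseline-proportional drug effect, and calibration of the statistical
layer. Both the test suite and the reproduction script call these.
"""

from __future__ import annotations

import itertools
import tempfile
from pathlib import Path

import numpy as np
from scipy import stats as ss

from . import _edf, pipeline, synthetic
from .cohort_stats import kruskal, ranksum, spearman
from .eeg_io import derive, read_recording, write_recording
from .features import ASIParams, asi, epoch_grid, reeg
from .preprocessing import bandpass, detect_artifacts
from .synthetic import CohortHeterogeneity, SimCohortConfig, SubjectSimParams
from .trends import ShortTermDesign, short_term_windows

FS = 250.0


# --------------------------------------------------------------------------
# range-EEG


def reeg_oracle_deviation(n_signals: int = 20, duration: float = 600.0, seed: int = 0) -> float:
    """Max |rEEG - brute-force scan| over seeded random signals (exact: 0)."""
    root = np.random.SeedSequence(seed).spawn(n_signals)
    w = int(2 * FS)
    worst = 0.0
    for ss_child in root:
        rng = np.random.default_rng(ss_child)
        x = rng.normal(0, 50, int(duration * FS))
        values = reeg(x, FS).values
        for i, v in enumerate(values):
            window = x[i * w : (i + 1) * w]
            mx = mn = window[0]
            for s in window[1:]:
                mx = s if s > mx else mx
                mn = s if s < mn else mn
            worst = max(worst, abs(v - (mx - mn)))
    return worst


def reeg_sine_max_error_pct(duration: float = 60.0) -> float:
    """Worst per-window deviation (%) from the 100 uV peak-to-peak of a
    50 uV-amplitude 5 Hz sine."""
    t = np.arange(0, duration, 1 / FS)
    values = reeg(50.0 * np.sin(2 * np.pi * 5.0 * t), FS).values
    return float(np.max(np.abs(values - 100.0)))


# --------------------------------------------------------------------------
# ASI


def asi_null_calibration(
    n_runs: int = 200, duration: float = 600.0, seed: int = 0
) -> tuple[float, float]:
    """(mean ASI, exceedance rate of the 95th-percentile surrogate
    threshold) for independent white-noise channel pairs."""
    children = np.random.SeedSequence(seed).spawn(n_runs)
    vals, exceed = [], []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        a = rng.normal(0, 1, int(duration * FS))
        b = rng.normal(0, 1, int(duration * FS))
        r = asi(a, b, FS, params=ASIParams(rng_seed=0), rng=rng, detail=True)
        vals.append(r.value)
        exceed.append(r.i0_bits > np.percentile(r.surrogate_bits, 95))
    return float(np.mean(vals)), float(np.mean(exceed))


def asi_sync_monotonicity(
    sync_grid=(0.0, 0.25, 0.5, 0.75, 1.0), n_seeds: int = 10, seed: int = 0
) -> dict[float, float]:
    """Median interhemispheric ASI of generated recordings per sync level."""
    cfg = SimCohortConfig(duration_pre=600.0, duration_post=600.0)
    out = {}
    base = np.random.SeedSequence(seed).generate_state(n_seeds * len(sync_grid))
    k = 0
    for sync in sync_grid:
        vals = []
        for _ in range(n_seeds):
            p = SubjectSimParams(sync_level=sync, rng_seed=int(base[k]) & 0x7FFFFFFF)
            k += 1
            rec = synthetic.synthesize_recording(p, cfg)
            sa, sb = derive(rec, "F3-P3"), derive(rec, "F4-P4")
            rng = np.random.default_rng(p.rng_seed)
            for t0 in epoch_grid(cfg.duration_pre):
                vals.append(
                    asi(sa, sb, FS, params=ASIParams(), rng=rng,
                        segment=(t0, t0 + 150.0))
                )
        out[sync] = float(np.nanmedian(vals))
    return out


# --------------------------------------------------------------------------
# artifact detection


def artifact_detection_performance(n_seeds: int = 20, seed: int = 0) -> tuple[float, float]:
    """(sensitivity, false-positive rate) on injected-artifact fixtures.

    Fixtures are 20-minute recordings with one 10-s artifact of each
    class; flagging is scored per 2-s segment against the injected
    intervals, guard-band segments counting as false positives.
    """
    classes = list(synthetic.ARTIFACT_CLASSES)
    hit = art_total = fp = clean_total = 0
    children = np.random.SeedSequence(seed).spawn(n_seeds)
    for child in children:
        rng = np.random.default_rng(child)
        onsets = [rng.uniform(100, 200), rng.uniform(400, 500), rng.uniform(800, 900)]
        rng.shuffle(classes)
        spec = [(c, float(o), 10.0) for c, o in zip(classes, onsets)]
        p = SubjectSimParams(rng_seed=int(rng.integers(2**31)), artifact_spec=spec)
        cfg = SimCohortConfig(duration_pre=600.0, duration_post=600.0)
        rec = synthetic.synthesize_recording(p, cfg)
        mask = detect_artifacts(bandpass(derive(rec, "F3"), FS), FS)
        times = mask.segment_times()
        is_art = np.zeros(mask.n_segments, dtype=bool)
        for _, onset, dur in spec:
            is_art |= (times + mask.segment_length > onset) & (times < onset + dur)
        invalid = ~mask.valid
        hit += int(invalid[is_art].sum())
        art_total += int(is_art.sum())
        fp += int(invalid[~is_art].sum())
        clean_total += int((~is_art).sum())
    return hit / art_total, fp / clean_total


# --------------------------------------------------------------------------
# design bookkeeping


def short_term_bookkeeping(drug_time: float = 7200.0) -> dict:
    baseline, post, grid_b, grid_p = short_term_windows(drug_time, ShortTermDesign())
    return {
        "baseline": baseline,
        "post": post,
        "n_epochs_baseline": int(grid_b.size),
        "n_epochs_post": int(grid_p.size),
        "n_long_term_epochs": int(epoch_grid(240.0 * 60.0).size),
    }


# --------------------------------------------------------------------------
# end-to-end parameter recovery


def recovery_significant_fraction(
    slope: float, n_cohorts: int = 50, n_subjects: int = 21, seed: int = 0
) -> float:
    """Fraction of synthetic cohorts where the delta-vs-baseline Spearman
    correlation of biparietal rEEG is negative with p < 0.05, with the
    full pipeline (filtering, artifact masking, epoch medians) in the loop."""
    cfg_a = pipeline.AnalysisConfig()
    cfg_a.reeg_derivations = ("P3-P4",)
    cfg_a.asi_pairs = {}
    het = CohortHeterogeneity(drug_effect_slope=slope)
    hits = 0
    children = np.random.SeedSequence(seed).generate_state(n_cohorts)
    for s in children:
        sim = SimCohortConfig(
            n_subjects=n_subjects, duration_pre=840.0, duration_post=720.0,
            rng_seed=int(s) & 0x7FFFFFFF,
        )
        table, _ = pipeline.cohort_short_term_table(
            (rec for _, rec in synthetic.iter_cohort(sim, het)), cfg_a
        )
        sub = table.dropna(subset=["baseline_median", "post_median"])
        r = spearman(sub["baseline_median"], sub["delta"])
        if r.computed and r.statistic < 0 and r.p_value < 0.05:
            hits += 1
    return hits / n_cohorts


# --------------------------------------------------------------------------
# statistical layer calibration


def _oracle_spearman_p(x, y) -> float:
    rx, ry = ss.rankdata(x), ss.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = total = 0
    for perm in itertools.permutations(ry):
        if abs(np.corrcoef(rx, np.array(perm))[0, 1]) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def _oracle_ranksum_p(a, b) -> float:
    pooled = np.concatenate([a, b])
    ranks = ss.rankdata(pooled)
    na, n = len(a), len(pooled)
    mean_w = na * (n + 1) / 2
    d = abs(ranks[:na].sum() - mean_w) - 1e-9
    hits = total = 0
    for combo in itertools.combinations(range(n), na):
        if abs(ranks[list(combo)].sum() - mean_w) >= d:
            hits += 1
        total += 1
    return hits / total


def _oracle_kruskal_p(groups) -> float:
    """Exact permutation p for H by enumerating group-label assignments."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)

    def h_stat(vals):
        r = ss.rankdata(vals)
        n = r.size
        start = 0
        h = 0.0
        for sz in sizes:
            h += sz * (r[start : start + sz].mean() - (n + 1) / 2) ** 2
            start += sz
        h *= 12 / (n * (n + 1))
        ties = np.unique(vals, return_counts=True)[1]
        correction = 1 - np.sum(ties**3 - ties) / (n**3 - n)
        return h / correction if correction > 0 else np.nan

    obs = h_stat(pooled)
    hits = total = 0
    for perm in itertools.permutations(range(pooled.size)):
        if h_stat(pooled[list(perm)]) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def stats_oracle_max_deviation(n_instances: int = 8, seed: int = 0) -> float:
    """Max |p - enumeration oracle p| for Spearman and rank-sum on random
    small instances (n <= 8), half of them with ties."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for k in range(n_instances):
        n = int(rng.integers(4, 9))
        x, y = rng.normal(size=n), rng.normal(size=n)
        if k % 2:
            x = np.round(x)
        worst = max(worst, abs(spearman(x, y).p_value - _oracle_spearman_p(x, y)))
        na, nb = int(rng.integers(2, 5)), int(rng.integers(2, 5))
        a, b = rng.normal(size=na), rng.normal(size=nb)
        if k % 2:
            a, b = np.round(a), np.round(b)
        worst = max(worst, abs(ranksum(a, b).p_value - _oracle_ranksum_p(a, b)))
    return worst


def type_one_error_rates(n_sims: int = 1000, alpha: float = 0.05, seed: int = 0) -> dict:
    """Null rejection rates of the three tests over seeded simulations."""
    rng = np.random.default_rng(seed)
    rej = {"spearman": 0, "wilcoxon_ranksum": 0, "kruskal_wallis": 0}
    for _ in range(n_sims):
        if spearman(rng.normal(size=20), rng.normal(size=20)).p_value < alpha:
            rej["spearman"] += 1
        if ranksum(rng.normal(size=8), rng.normal(size=8)).p_value < alpha:
            rej["wilcoxon_ranksum"] += 1
        if kruskal([rng.normal(size=8) for _ in range(3)]).p_value < alpha:
            rej["kruskal_wallis"] += 1
    return {k: v / n_sims for k, v in rej.items()}


# --------------------------------------------------------------------------
# EDF round trip


def edf_roundtrip_max_error(n_subjects: int = 3, seed: int = 0) -> float:
    """Max |written - re-read| sample error (uV) over a small synthetic
    cohort written to EDF and read back; must be within one 16-bit step."""
    cfg = SimCohortConfig(n_subjects=n_subjects, duration_pre=60.0, duration_post=60.0,
                          rng_seed=seed)
    het = CohortHeterogeneity(artifact_rate_per_recording=0.0)
    worst = 0.0
    with tempfile.TemporaryDirectory() as tmp:
        for p, rec in synthetic.iter_cohort(cfg, het):
            path = write_recording(rec, Path(tmp) / f"{p.subject_id}.edf")
            back, _ = read_recording(path, subject_id=p.subject_id)
            worst = max(worst, float(np.max(np.abs(back.samples - rec.samples))))
    return worst
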