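"""Synthetic discontinuous neonatal-like EEG with known ground truth.

Preterm and term neonatal EEG alternates between high-amplitude
activity bursts (spontaneous activity transients, SATs) and
low-amplitude interburst intervals ("trace discontinu"). The generator
emulates exactly the statistical structure the downstream features
measure, with every parameter recorded as ground truth:

* burst timing: a renewal process with lognormal burst durations and
  interburst intervals;
* burst waveform: band-limited (1-20 Hz) noise under a half-sine
  envelope, peak-to-peak scaled to the subject's baseline amplitude;
* interhemispheric synchrony: each left-hemisphere burst is copied to
  the right hemisphere with probability ``sync_level`` (onset jitter
  <= 0.2 s); unshared bursts are replaced by an independent train so
  both hemispheres keep the same burst rate;
* a sedative step effect at the drug timestamp: burst amplitude and
  synchrony are both multiplied by ``max(0, 1 - slope * b)`` where
  ``b`` is the subject's baseline amplitude normalised to the cohort
  maximum, so subjects with more baseline activity lose more —
  the baseline-proportional effect the analysis is designed to detect;
* injectable artifacts of three classes (amplitude excursions,
  sustained 25-35 Hz oscillation, < 0.3 Hz high-voltage drift).

Nothing here claims spectral or sleep-state fidelity; see the methods
note for what the generator does and does not emulate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .eeg_io import EEGRecording, REQUIRED_CHANNELS

# left hemisphere: F3, P3; right hemisphere: F4, P4
_LEFT = ("F3", "P3")
_RIGHT = ("F4", "P4")

INTRA_HEMISPHERE_SYNC = 0.9  # frontal/parietal burst sharing within a hemisphere

ARTIFACT_CLASSES = ("amplitude", "high_freq", "low_freq")


@dataclass
class SubjectSimParams:
    """Ground-truth generating parameters for one synthetic subject."""

    subject_id: str = "sim"
    baseline_amplitude: float = 75.0      # uV, burst peak-to-peak
    sync_level: float = 0.7               # P(burst shared across hemispheres)
    drug_effect_slope: float = 0.0        # fractional reduction per unit normalised baseline
    burst_duration_mean: float = 3.0      # s
    ibi_mean: float = 6.0                 # s
    burst_rate: float | None = None       # bursts/min; derived from durations if None
    artifact_spec: list[tuple[str, float, float]] = field(default_factory=list)
    rng_seed: int = 0
    normalized_baseline: float | None = None  # set by the cohort generator

    def __post_init__(self) -> None:
        if not 0.0 <= self.sync_level <= 1.0:
            raise ValueError("sync_level must be in [0, 1]")
        if self.burst_duration_mean <= 0 or self.ibi_mean <= 0:
            raise ValueError("burst_duration_mean and ibi_mean must be positive")
        if self.drug_effect_slope < 0:
            raise ValueError("drug_effect_slope must be >= 0")
        implied = 60.0 / (self.burst_duration_mean + self.ibi_mean)
        if self.burst_rate is None:
            self.burst_rate = implied
        elif abs(self.burst_rate - implied) > 0.2 * implied:
            raise ValueError(
                f"burst_rate {self.burst_rate:.2f}/min inconsistent with "
                f"durations (implies {implied:.2f}/min)"
            )
        for kind, onset, dur in self.artifact_spec:
            if kind not in ARTIFACT_CLASSES:
                raise ValueError(f"unknown artifact class {kind!r}")
            if dur <= 0:
                raise ValueError("artifact duration must be positive")

    @property
    def baseline_norm(self) -> float:
        """Baseline amplitude normalised to [0, 1] for the drug effect."""
        if self.normalized_baseline is not None:
            return self.normalized_baseline
        return min(1.0, self.baseline_amplitude / 150.0)

    @property
    def drug_factor(self) -> float:
        """Multiplier applied to amplitude and synchrony after the drug."""
        return max(0.0, 1.0 - self.drug_effect_slope * self.baseline_norm)


@dataclass
class SimCohortConfig:
    """Cohort-level recording geometry (matches the study design)."""

    n_subjects: int = 21
    duration_pre: float = 7200.0   # s before drug administration
    duration_post: float = 7200.0  # s after
    sampling_rate: float = 250.0   # Hz
    rng_seed: int = 0

    channels: tuple[str, ...] = REQUIRED_CHANNELS

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.duration_pre <= 0 or self.duration_post <= 0:
            raise ValueError("durations must be positive")
        if self.sampling_rate <= 2 * 35.0:
            raise ValueError("sampling_rate must exceed twice the highest synthesized frequency")


@dataclass
class CohortHeterogeneity:
    """Across-subject parameter ranges for cohort synthesis."""

    baseline_amplitude_range: tuple[float, float] = (25.0, 150.0)   # uV
    sync_level_range: tuple[float, float] = (0.4, 0.9)
    drug_effect_slope: float = 0.5
    artifact_rate_per_recording: float = 2.0    # mean count, Poisson
    artifact_duration_range: tuple[float, float] = (5.0, 15.0)      # s

    def __post_init__(self) -> None:
        lo, hi = self.baseline_amplitude_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid baseline_amplitude_range")
        lo, hi = self.sync_level_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("invalid sync_level_range")
        if self.baseline_amplitude_range[0] == self.baseline_amplitude_range[1]:
            warnings.warn("degenerate heterogeneity: zero amplitude variance", stacklevel=2)


# ---------------------------------------------------------------------------
# burst trains


def _lognormal(rng: np.random.Generator, mean: float, sigma: float, size: int) -> np.ndarray:
    """Lognormal draws with the requested arithmetic mean."""
    mu = math.log(mean) - sigma**2 / 2.0
    return rng.lognormal(mu, sigma, size)


def _renewal_train(
    rng: np.random.Generator,
    duration: float,
    dur_mean: float,
    ibi_mean: float,
    dur_sigma: float = 0.35,
    ibi_sigma: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Burst (onset, duration) arrays from a renewal process on [0, duration)."""
    cycle = dur_mean + ibi_mean
    n_max = int(duration / cycle * 2.5) + 10
    durs = _lognormal(rng, dur_mean, dur_sigma, n_max)
    ibis = _lognormal(rng, ibi_mean, ibi_sigma, n_max)
    onsets = rng.uniform(0, cycle) + np.concatenate(([0.0], np.cumsum(durs + ibis)[:-1]))
    keep = onsets + durs < duration
    return onsets[keep], durs[keep]


def _merge_trains(
    primary: tuple[np.ndarray, np.ndarray],
    extra: tuple[np.ndarray, np.ndarray],
    min_gap: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Union of two burst trains, dropping extras that would overlap
    (overlapping bursts would sum and break amplitude conservation)."""
    p_on, p_dur = primary
    e_on, e_dur = extra
    keep = np.ones(e_on.size, dtype=bool)
    for k, (o, d) in enumerate(zip(e_on, e_dur)):
        if np.any((o < p_on + p_dur + min_gap) & (o + d + min_gap > p_on)):
            keep[k] = False
    on = np.concatenate([p_on, e_on[keep]])
    dur = np.concatenate([p_dur, e_dur[keep]])
    order = np.argsort(on)
    return on[order], dur[order]


def _hemisphere_trains(
    rng: np.random.Generator, duration: float, params: SubjectSimParams, sync: float
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Burst trains for both hemispheres with the requested coupling."""
    left_on, left_dur = _renewal_train(rng, duration, params.burst_duration_mean, params.ibi_mean)
    shared = rng.random(left_on.size) < sync
    jitter = rng.uniform(-0.2, 0.2, left_on.size)
    r_on = np.clip(left_on[shared] + jitter[shared], 0.0, None)
    r_dur = left_dur[shared]
    # independent replacement bursts keep the right-hemisphere rate equal
    ind_on, ind_dur = _renewal_train(rng, duration, params.burst_duration_mean, params.ibi_mean)
    keep = rng.random(ind_on.size) < (1.0 - sync)
    right = _merge_trains((r_on, r_dur), (ind_on[keep], ind_dur[keep]))
    return {"L": (left_on, left_dur), "R": right}


def _channel_trains(
    rng: np.random.Generator,
    duration: float,
    params: SubjectSimParams,
    hemi: tuple[np.ndarray, np.ndarray],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Split a hemisphere train into frontal/parietal channel trains."""
    on, dur = hemi
    frontal = (on, dur)
    keep = rng.random(on.size) < INTRA_HEMISPHERE_SYNC
    extra_on, extra_dur = _renewal_train(
        rng, duration, params.burst_duration_mean, params.ibi_mean
    )
    k2 = rng.random(extra_on.size) < (1.0 - INTRA_HEMISPHERE_SYNC)
    parietal = _merge_trains((on[keep], dur[keep]), (extra_on[k2], extra_dur[k2]))
    return {"frontal": frontal, "parietal": parietal}


# ---------------------------------------------------------------------------
# waveform rendering


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance noise band-limited to the burst band (1-20 Hz)."""
    sos = sps.butter(4, [1.0, 20.0], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


_BG_PP_FRACTION = 0.10  # interburst background peak-to-peak vs burst amplitude


def _render_channel(
    rng: np.random.Generator,
    n: int,
    fs: float,
    onsets: np.ndarray,
    durs: np.ndarray,
    amplitude: float,
) -> np.ndarray:
    """One channel: continuous background plus enveloped burst snippets."""
    noise = _bandlimited_noise(rng, n, fs)
    bg_sigma = _BG_PP_FRACTION * amplitude / 6.0  # ~6 sigma spans the p-p
    x = noise * bg_sigma
    src = _bandlimited_noise(rng, n, fs)
    pp_jitter = rng.uniform(0.95, 1.05, onsets.size)
    for onset, dur, jit in zip(onsets, durs, pp_jitter):
        i0 = int(round(onset * fs))
        i1 = min(int(round((onset + dur) * fs)), n)
        if i1 - i0 < 4:
            continue
        env = np.sin(np.pi * np.linspace(0.0, 1.0, i1 - i0))
        snippet = src[i0:i1] * env
        pp = snippet.max() - snippet.min()
        if pp <= 0:
            continue
        x[i0:i1] += snippet * (amplitude * jit / pp)
    return x


def _inject_artifact(
    rng: np.random.Generator, x: np.ndarray, fs: float, kind: str, onset: float, dur: float
) -> None:
    """Add one artifact in place; waveform phase/polarity is channel-specific."""
    n = x.size
    i0 = max(0, int(round(onset * fs)))
    i1 = min(n, int(round((onset + dur) * fs)))
    if i1 <= i0:
        return
    t = np.arange(i1 - i0) / fs
    if kind == "amplitude":
        # rail-to-rail excursions: +-1200 uV square alternating at 1 Hz,
        # channel-specific phase so bipolar derivations do not cancel
        phase = rng.uniform(0, 1)
        x[i0:i1] += 1200.0 * np.sign(np.sin(2 * np.pi * (t + phase)))
    elif kind == "high_freq":
        x[i0:i1] += 80.0 * np.sin(2 * np.pi * 30.0 * t + rng.uniform(0, 2 * np.pi))
    elif kind == "low_freq":
        x[i0:i1] += 250.0 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    else:  # pragma: no cover - validated upstream
        raise ValueError(kind)


# ---------------------------------------------------------------------------
# public operations


def synthesize_recording(
    params: SubjectSimParams,
    cfg: SimCohortConfig | None = None,
    return_truth: bool = False,
):
    """Synthesize one 4-channel recording; drug step at ``cfg.duration_pre``.

    With ``return_truth=True`` also returns a dict holding the exact
    burst trains per channel and segment, for generator-level checks.
    """
    cfg = cfg or SimCohortConfig()
    fs = cfg.sampling_rate
    min_len = params.burst_duration_mean + params.ibi_mean
    if cfg.duration_pre < min_len or cfg.duration_post < min_len:
        raise ValueError(
            f"segment shorter than one burst cycle ({min_len:.1f} s); "
            "increase duration_pre/duration_post"
        )
    rng = np.random.default_rng(params.rng_seed)
    f = params.drug_factor

    segments = {
        "pre": (cfg.duration_pre, params.baseline_amplitude, params.sync_level),
        "post": (cfg.duration_post, params.baseline_amplitude * f, params.sync_level * f),
    }
    chans = {ch: [] for ch in cfg.channels}
    truth: dict = {"trains": {}, "drug_factor": f, "params": params}
    for seg_name, (duration, amp, sync) in segments.items():
        n = int(round(duration * fs))
        hemis = _hemisphere_trains(rng, duration, params, sync)
        truth["trains"][seg_name] = {"L": hemis["L"], "R": hemis["R"]}
        for side, (fch, pch) in (("L", _LEFT), ("R", _RIGHT)):
            per_ch = _channel_trains(rng, duration, params, hemis[side])
            for ch, key in ((fch, "frontal"), (pch, "parietal")):
                on, dur = per_ch[key]
                chans[ch].append(_render_channel(rng, n, fs, on, dur, amp))
                truth["trains"][seg_name][ch] = (on, dur)

    samples = np.vstack([np.concatenate(chans[ch]) for ch in cfg.channels])
    for kind, onset, dur in params.artifact_spec:
        for row in samples:
            _inject_artifact(rng, row, fs, kind, onset, dur)

    rec = EEGRecording(
        samples=samples,
        sampling_rate=fs,
        channel_labels=list(cfg.channels),
        drug_time=cfg.duration_pre,
        subject_id=params.subject_id,
    )
    if return_truth:
        return rec, truth
    return rec


def draw_cohort_params(
    cfg: SimCohortConfig, het: CohortHeterogeneity | None = None
) -> tuple[list[SubjectSimParams], pd.DataFrame]:
    """Draw per-subject parameters and clinical covariates reproducibly.

    Returns the parameter list plus the ground-truth table recording
    every drawn value, including the construction-level drug effect
    (``true_delta_amplitude``) each subject will express.
    """
    het = het or CohortHeterogeneity()
    ss = np.random.SeedSequence(cfg.rng_seed)
    master = np.random.default_rng(ss)
    child_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(cfg.n_subjects)]

    amps = master.uniform(*het.baseline_amplitude_range, cfg.n_subjects)
    syncs = master.uniform(*het.sync_level_range, cfg.n_subjects)
    amp_max = float(np.max(amps))
    # clinical covariates mirror the study demographics: GA 27-42 weeks,
    # 12/21 on fentanyl, diagnosis groups sized 5/8/6/2
    ga_days = master.integers(27 * 7, 42 * 7 + 1, cfg.n_subjects)
    fentanyl = master.random(cfg.n_subjects) < 12 / 21
    diagnosis = master.choice(4, size=cfg.n_subjects, p=np.array([5, 8, 6, 2]) / 21)

    duration = cfg.duration_pre + cfg.duration_post
    params_list: list[SubjectSimParams] = []
    rows = []
    for i in range(cfg.n_subjects):
        n_art = int(master.poisson(het.artifact_rate_per_recording))
        artifacts = [
            (
                str(master.choice(ARTIFACT_CLASSES)),
                float(master.uniform(0, duration - het.artifact_duration_range[1])),
                float(master.uniform(*het.artifact_duration_range)),
            )
            for _ in range(n_art)
        ]
        p = SubjectSimParams(
            subject_id=f"sim{i:02d}",
            baseline_amplitude=float(amps[i]),
            sync_level=float(syncs[i]),
            drug_effect_slope=het.drug_effect_slope,
            artifact_spec=artifacts,
            rng_seed=child_seeds[i],
            normalized_baseline=float(amps[i] / amp_max),
        )
        params_list.append(p)
        rows.append(
            {
                "subject_id": p.subject_id,
                "baseline_amplitude": p.baseline_amplitude,
                "sync_level": p.sync_level,
                "drug_effect_slope": p.drug_effect_slope,
                "normalized_baseline": p.normalized_baseline,
                "drug_factor": p.drug_factor,
                "true_delta_amplitude": p.baseline_amplitude * (p.drug_factor - 1.0),
                "gestational_age_days": int(ga_days[i]),
                "fentanyl": int(fentanyl[i]),
                "diagnosis_group": int(diagnosis[i]),
                "n_artifacts": n_art,
                "drug_time_s": cfg.duration_pre,
                "seed": child_seeds[i],
            }
        )
    return params_list, pd.DataFrame(rows)


def iter_cohort(cfg: SimCohortConfig, het: CohortHeterogeneity | None = None):
    """Lazily yield (params, recording) pairs; memory stays per-subject."""
    params_list, truth = draw_cohort_params(cfg, het)
    for p in params_list:
        yield p, synthesize_recording(p, cfg)


def synthesize_cohort(
    cfg: SimCohortConfig, het: CohortHeterogeneity | None = None
) -> tuple[list[EEGRecording], pd.DataFrame]:
    """Synthesize the whole cohort in memory plus its ground-truth table."""
    params_list, truth = draw_cohort_params(cfg, het)
    recs = [synthesize_recording(p, cfg) for p in params_list]
    return recs, truth


def cooccurrence_fraction(
    train_a: tuple[np.ndarray, np.ndarray],
    train_b: tuple[np.ndarray, np.ndarray],
    tolerance: float = 0.5,
) -> float:
    """Fraction of bursts in train_a with a train_b onset within tolerance."""
    on_a = np.asarray(train_a[0])
    on_b = np.asarray(train_b[0])
    if on_a.size == 0:
        return float("nan")
    idx = np.searchsorted(on_b, on_a)
    best = np.full(on_a.size, np.inf)
    for off in (-1, 0):
        j = np.clip(idx + off, 0, on_b.size - 1)
        best = np.minimum(best, np.abs(on_b[j] - on_a))
    return float(np.mean(best <= tolerance))
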