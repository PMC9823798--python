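"""The two bedside trend features: range-EEG and the Activation Synchrony Index.

Range-EEG (rEEG) is the peak-to-peak amplitude (max minus min) of each
non-overlapping 2-second window — an objective analogue of the aEEG
amplitude trend. The Activation Synchrony Index (ASI) quantifies how
often activity bursts co-occur between two EEG signals: the amplitude
envelopes of both signals are quantised and their mutual information at
zero lag is compared against a circular-shift surrogate null, so that
independent channels score ~0 and perfectly co-bursting channels score
highly. Both features are computed per 2.5-minute epoch for trend
display and for the pre/post drug statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eeg_io import EEGRecording, derive
from .preprocessing import ArtifactMask

EPOCH_LENGTH = 150.0  # s, the 2.5-minute analysis epoch
MIN_VALID_FRACTION = 0.5


@dataclass
class FeatureTrend:
    """Windowed or epoched values of one feature on one derivation."""

    feature: str              # "rEEG" or "ASI"
    name: str                 # derivation or derivation-pair label
    times: np.ndarray         # window/epoch start, s
    values: np.ndarray        # uV (rEEG) or unitless (ASI); NaN = missing
    window_length: float      # s

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must align")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def reeg(
    signal: np.ndarray,
    sampling_rate: float,
    mask: ArtifactMask | np.ndarray | None = None,
    window: float = 2.0,
    name: str = "",
) -> FeatureTrend:
    """Per-window peak-to-peak amplitude; masked windows are NaN.

    Windows are non-overlapping and anchored at t=0; a trailing partial
    window is dropped. Values are in the signal's units (uV).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    x = np.asarray(signal, dtype=float)
    w = int(round(window * sampling_rate))
    n_win = x.size // w
    if n_win == 0:
        return FeatureTrend("rEEG", name, np.empty(0), np.empty(0), window)
    segs = x[: n_win * w].reshape(n_win, w)
    values = segs.max(axis=1) - segs.min(axis=1)
    if mask is not None:
        valid = mask.valid if isinstance(mask, ArtifactMask) else np.asarray(mask, bool)
        values = np.where(valid[:n_win], values, np.nan)
    times = np.arange(n_win) * window
    return FeatureTrend("rEEG", name, times, values, window)


def running_mean(values: np.ndarray, k: int = 5) -> np.ndarray:
    """Centered moving average over k windows, NaN-aware, shrinking at edges.

    This is the smoothed series used for trend display; the raw window
    values always feed the epoch statistics.
    """
    v = np.asarray(values, dtype=float)
    half = k // 2
    out = np.full_like(v, np.nan)
    for i in range(v.size):
        lo, hi = max(0, i - half), min(v.size, i + half + 1)
        win = v[lo:hi]
        if np.any(np.isfinite(win)):
            out[i] = np.nanmean(win)
    return out


@dataclass
class ASIParams:
    """Constants of the ASI instantiation (envelope / quantise / MI / null)."""

    envelope_window: float = 1.0   # s, RMS envelope bin
    n_bins: int = 4                # quantisation levels (quartiles)
    n_surrogates: int = 100
    min_shift: float = 30.0        # s, minimum circular surrogate shift
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.n_surrogates < 20:
            raise ValueError("n_surrogates must be >= 20")


@dataclass
class ASIResult:
    value: float               # log2(I0 / median surrogate MI); NaN if missing
    i0_bits: float
    surrogate_bits: np.ndarray


_MI_FLOOR = 1e-6  # bits; guards the surrogate-ratio denominator


def _rank_quantize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-occupancy quantisation by rank (exact quantile bins).

    Rank-based binning makes the downstream mutual information exactly
    invariant to any monotone rescaling of the envelope.
    """
    order = np.argsort(x, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(x.size)
    return (ranks * n_bins) // x.size


def _mutual_information_bits(qa: np.ndarray, qb: np.ndarray, n_bins: int) -> float:
    joint = np.bincount(qa * n_bins + qb, minlength=n_bins * n_bins).astype(float)
    n = joint.sum()
    pj = joint / n
    pa = pj.reshape(n_bins, n_bins).sum(axis=1)
    pb = pj.reshape(n_bins, n_bins).sum(axis=0)
    nz = pj > 0
    outer = np.outer(pa, pb).ravel()
    return float(np.sum(pj[nz] * np.log2(pj[nz] / outer[nz])))


def _envelope(x: np.ndarray, sampling_rate: float, envelope_window: float) -> np.ndarray:
    w = int(round(envelope_window * sampling_rate))
    n = x.size // w
    segs = x[: n * w].reshape(n, w)
    return np.sqrt(np.mean(segs**2, axis=1))


def asi(
    signal_a: np.ndarray,
    signal_b: np.ndarray,
    sampling_rate: float,
    valid: np.ndarray | None = None,
    params: ASIParams | None = None,
    segment: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
    detail: bool = False,
):
    """Activation Synchrony Index between two signals over a segment.

    ``valid`` is per-2-s-segment validity (the shared artifact grid)
    covering the whole signal; only jointly valid envelope bins enter
    the estimate. Returns NaN when less than half the segment is valid
    or when an envelope is degenerate (zero variance).
    """
    params = params or ASIParams()
    rng = rng or np.random.default_rng(params.rng_seed)
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    if a.size != b.size:
        raise ValueError("signals must have equal length")
    if segment is not None:
        i0 = int(round(segment[0] * sampling_rate))
        i1 = int(round(segment[1] * sampling_rate))
        a, b = a[i0:i1], b[i0:i1]
    else:
        i0 = 0

    env_a = _envelope(a, sampling_rate, params.envelope_window)
    env_b = _envelope(b, sampling_rate, params.envelope_window)
    n_env = env_a.size
    if n_env < 4 * params.n_bins:
        return ASIResult(np.nan, np.nan, np.empty(0)) if detail else np.nan

    if valid is None:
        keep = np.ones(n_env, dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool)
        # map each envelope bin to the 2-s artifact segment containing it
        starts = i0 / sampling_rate + np.arange(n_env) * params.envelope_window
        seg_idx = np.minimum((starts / 2.0).astype(int), valid.size - 1)
        keep = valid[seg_idx]
    if keep.mean() < MIN_VALID_FRACTION:
        return ASIResult(np.nan, np.nan, np.empty(0)) if detail else np.nan

    ea, eb = env_a[keep], env_b[keep]
    if np.ptp(ea) <= 0 or np.ptp(eb) <= 0:
        warnings.warn("zero-variance envelope; ASI undefined", stacklevel=2)
        return ASIResult(np.nan, np.nan, np.empty(0)) if detail else np.nan

    qa = _rank_quantize(ea, params.n_bins)
    qb = _rank_quantize(eb, params.n_bins)
    i0_bits = _mutual_information_bits(qa, qb, params.n_bins)

    n = qa.size
    min_shift_bins = max(1, int(round(params.min_shift / params.envelope_window)))
    if 2 * min_shift_bins >= n:
        min_shift_bins = max(1, n // 4)
    shifts = rng.integers(min_shift_bins, n - min_shift_bins, params.n_surrogates)
    sur = np.array(
        [_mutual_information_bits(qa, np.roll(qb, s), params.n_bins) for s in shifts]
    )
    value = math.log2(max(i0_bits, _MI_FLOOR) / max(float(np.median(sur)), _MI_FLOOR))
    if detail:
        return ASIResult(value, i0_bits, sur)
    return value


# ---------------------------------------------------------------------------
# epoch-level feature computation

# the derivation pairs the synchrony analysis compares
ASI_PAIRS = {
    "interhemispheric": ("F3-P3", "F4-P4"),
    "intra_left": ("F3", "P3"),
    "intra_right": ("F4", "P4"),
    "frontal": ("F3", "F4"),
}


def epoch_grid(duration: float, epoch_length: float = EPOCH_LENGTH) -> np.ndarray:
    """Start times of complete epochs tiling [0, duration)."""
    n = int(duration / epoch_length)
    return np.arange(n) * epoch_length


def reeg_epochs(
    trend: FeatureTrend, duration: float, epoch_length: float = EPOCH_LENGTH
) -> FeatureTrend:
    """Mean of valid rEEG window values per epoch; NaN below 50% validity."""
    starts = epoch_grid(duration, epoch_length)
    per_epoch = int(round(epoch_length / trend.window_length))
    out = np.full(starts.size, np.nan)
    for k, t0 in enumerate(starts):
        sel = (trend.times >= t0) & (trend.times < t0 + epoch_length)
        vals = trend.values[sel]
        if vals.size and np.isfinite(vals).sum() >= MIN_VALID_FRACTION * per_epoch:
            out[k] = np.nanmean(vals)
    return FeatureTrend("rEEG", trend.name, starts, out, epoch_length)


def feature_over_epochs(
    rec: EEGRecording,
    masks: dict[str, ArtifactMask],
    derivations: tuple[str, ...] = ("P3-P4", "F3-F4", "F3", "F4", "P3", "P4", "F3-P3", "F4-P4"),
    asi_pairs: dict[str, tuple[str, str]] | None = None,
    asi_params: ASIParams | None = None,
    epoch_length: float = EPOCH_LENGTH,
    signals: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Tidy per-epoch feature table for one recording.

    ``masks`` maps derivation name to its ArtifactMask; ``signals``
    optionally supplies pre-filtered derivation signals (else raw
    derivations are used as-is). Columns: subject_id, feature, name,
    epoch_start, value.
    """
    asi_pairs = ASI_PAIRS if asi_pairs is None else asi_pairs
    asi_params = asi_params or ASIParams()
    fs = rec.sampling_rate
    duration = rec.duration
    starts = epoch_grid(duration, epoch_length)

    def get_signal(name: str) -> np.ndarray:
        if signals is not None and name in signals:
            return signals[name]
        return derive(rec, name)

    rows = []
    for name in derivations:
        sig = get_signal(name)
        mask = masks.get(name)
        valid = mask.valid if mask is not None else None
        trend = reeg(sig, fs, mask=valid, name=name)
        ep = reeg_epochs(trend, duration, epoch_length)
        for t0, v in zip(ep.times, ep.values):
            rows.append(
                {"subject_id": rec.subject_id, "feature": "rEEG", "name": name,
                 "epoch_start": t0, "value": v}
            )

    rng = np.random.default_rng(asi_params.rng_seed)
    for pair_name, (da, db) in asi_pairs.items():
        sa, sb = get_signal(da), get_signal(db)
        ma, mb = masks.get(da), masks.get(db)
        if ma is not None and mb is not None:
            joint = ma.valid & mb.valid
        elif ma is not None or mb is not None:
            joint = (ma or mb).valid
        else:
            joint = None
        for t0 in starts:
            v = asi(sa, sb, fs, valid=joint, params=asi_params,
                    segment=(t0, t0 + epoch_length), rng=rng)
            rows.append(
                {"subject_id": rec.subject_id, "feature": "ASI", "name": pair_name,
                 "epoch_start": t0, "value": v}
            )
    return pd.DataFrame(rows)
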