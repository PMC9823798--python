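"""Range-EEG and Activation Synchrony Index behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoqeeg.eeg_io import derive
from neoqeeg.features import (
    ASIParams,
    asi,
    epoch_grid,
    feature_over_epochs,
    reeg,
    reeg_epochs,
    running_mean,
)
from neoqeeg.preprocessing import ArtifactMask, detect_artifacts, bandpass
from neoqeeg.synthetic import SimCohortConfig, SubjectSimParams, synthesize_recording

FS = 250.0


def brute_force_reeg(x, w):
    """Independent oracle: explicit per-window max-minus-min scan."""
    out = []
    for i in range(len(x) // w):
        window = list(x[i * w : (i + 1) * w])
        mx = mn = window[0]
        for v in window[1:]:
            mx = v if v > mx else mx
            mn = v if v < mn else mn
        out.append(mx - mn)
    return np.array(out)


def test_reeg_constant_signal_zero():
    tr = reeg(np.full(int(10 * FS), 42.0), FS)
    assert np.all(tr.values == 0.0)


def test_reeg_sine_peak_to_peak():
    t = np.arange(0, 20, 1 / FS)
    tr = reeg(50.0 * np.sin(2 * np.pi * 5.0 * t), FS)
    assert np.all(np.abs(tr.values - 100.0) < 1.0)  # within 1%


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_reeg_equals_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 50, int(rng.integers(3, 12) * FS))
    tr = reeg(x, FS)
    assert np.array_equal(tr.values, brute_force_reeg(x, int(2 * FS)))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.floats(-100, 100))
def test_reeg_invariant_to_negation_and_offset(seed, offset):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 50, int(8 * FS))
    base = reeg(x, FS).values
    assert np.allclose(reeg(-x, FS).values, base)
    assert np.allclose(reeg(x + offset, FS).values, base)


def test_reeg_empty_for_short_signal():
    assert reeg(np.zeros(10), FS).values.size == 0


def test_reeg_masked_windows_missing():
    x = np.tile([0.0, 10.0], int(6 * FS / 2))
    valid = np.array([True, False, True])
    tr = reeg(x, FS, mask=valid)
    assert np.isnan(tr.values[1]) and np.isfinite(tr.values[[0, 2]]).all()


def test_running_mean_centered_shrinking():
    v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    rm = running_mean(v, k=3)
    assert rm[0] == pytest.approx(1.5)   # shrunk edge window
    assert rm[2] == pytest.approx(3.0)
    assert rm[4] == pytest.approx(4.5)


def test_asi_identical_channels_saturates():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, int(600 * FS))
    r = asi(x, x, FS, detail=True)
    assert r.i0_bits == pytest.approx(np.log2(4), abs=1e-12)
    assert r.i0_bits > np.percentile(r.surrogate_bits, 99)
    assert r.value > 0


def test_asi_independent_noise_near_zero():
    vals = []
    for seed in range(30):
        rng = np.random.default_rng(1000 + seed)
        a = rng.normal(0, 1, int(600 * FS))
        b = rng.normal(0, 1, int(600 * FS))
        vals.append(asi(a, b, FS, params=ASIParams(rng_seed=seed)))
    assert abs(np.mean(vals)) < 0.15


def test_asi_invariant_to_monotone_rescaling():
    """Rank quantisation makes ASI exactly invariant to monotone amplitude
    rescaling of either channel (same surrogate draws)."""
    rng = np.random.default_rng(3)
    a = rng.normal(0, 1, int(300 * FS))
    b = 0.5 * a + rng.normal(0, 1, int(300 * FS))
    params = ASIParams(rng_seed=7)
    v1 = asi(a, b, FS, params=params)
    v2 = asi(3.7 * a, b, FS, params=params)    # gain on one channel
    v3 = asi(3.7 * a, 0.01 * b, FS, params=params)  # and on the other
    assert v1 == pytest.approx(v2, abs=1e-12)
    assert v1 == pytest.approx(v3, abs=1e-12)


def test_asi_sync_grid_monotone():
    meds = []
    for sync in (0.0, 0.5, 1.0):
        vals = []
        for seed in range(3):
            p = SubjectSimParams(sync_level=sync, rng_seed=300 + seed)
            cfg = SimCohortConfig(duration_pre=600, duration_post=600)
            rec = synthesize_recording(p, cfg)
            sa, sb = derive(rec, "F3-P3"), derive(rec, "F4-P4")
            for k in range(4):
                vals.append(asi(sa, sb, FS, params=ASIParams(rng_seed=seed),
                                segment=(k * 150.0, (k + 1) * 150.0)))
        meds.append(np.median(vals))
    assert meds[0] < meds[1] < meds[2]


def test_asi_zero_variance_envelope_missing():
    x = np.ones(int(200 * FS))
    rng = np.random.default_rng(0)
    y = rng.normal(0, 1, x.size)
    with pytest.warns(UserWarning, match="zero-variance"):
        assert np.isnan(asi(x, y, FS))


def test_asi_insufficient_valid_data_missing():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 1, int(200 * FS))
    b = rng.normal(0, 1, int(200 * FS))
    valid = np.zeros(100, bool)  # everything masked
    assert np.isnan(asi(a, b, FS, valid=valid))


def test_epoch_grid_counts():
    assert epoch_grid(240 * 60).size == 96   # 4-hour recording, 2.5-min epochs
    assert epoch_grid(600).size == 4
    assert epoch_grid(149.0).size == 0


def test_reeg_epochs_stationary_signal():
    t = np.arange(0, 600, 1 / FS)
    tr = reeg(40 * np.sin(2 * np.pi * 4 * t), FS)
    ep = reeg_epochs(tr, 600.0)
    assert ep.values.size == 4
    assert np.ptp(ep.values) / np.mean(ep.values) < 0.02


def test_fully_masked_epoch_missing():
    t = np.arange(0, 600, 1 / FS)
    x = 40 * np.sin(2 * np.pi * 4 * t)
    valid = np.ones(300, bool)
    valid[75:150] = False  # second epoch entirely invalid
    tr = reeg(x, FS, mask=valid)
    ep = reeg_epochs(tr, 600.0)
    assert np.isnan(ep.values[1])
    assert np.isfinite(ep.values[[0, 2, 3]]).all()


def test_feature_over_epochs_tidy_table():
    p = SubjectSimParams(rng_seed=41)
    cfg = SimCohortConfig(duration_pre=300, duration_post=300)
    rec = synthesize_recording(p, cfg)
    masks = {}
    for name in ("P3-P4", "F3-P3", "F4-P4"):
        masks[name] = detect_artifacts(bandpass(derive(rec, name), FS), FS)
    table = feature_over_epochs(
        rec, masks, derivations=("P3-P4",),
        asi_pairs={"interhemispheric": ("F3-P3", "F4-P4")},
    )
    n_epochs = epoch_grid(rec.duration).size
    assert set(table["feature"]) == {"rEEG", "ASI"}
    assert (table.groupby(["feature", "name"]).size() == n_epochs).all()
    reeg_vals = table[table.feature == "rEEG"]["value"]
    assert (reeg_vals.dropna() >= 0).all()
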