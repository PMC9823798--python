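"""Generator-level checks: the synthetic cohort's ground truth must hold
by construction before any signal processing is trusted with it."""

import numpy as np
import pytest
from scipy import stats as ss

from neoqeeg.synthetic import (
    CohortHeterogeneity,
    SimCohortConfig,
    SubjectSimParams,
    cooccurrence_fraction,
    draw_cohort_params,
    synthesize_cohort,
    synthesize_recording,
)

FS = 250.0


def _burst_pp(signal, fs, train):
    """Realized peak-to-peak of each burst in a channel."""
    onsets, durs = train
    pps = []
    for o, d in zip(onsets, durs):
        seg = signal[int(o * fs) : int((o + d) * fs)]
        if seg.size:
            pps.append(seg.max() - seg.min())
    return np.array(pps)


def test_seeded_determinism():
    p = SubjectSimParams(rng_seed=3)
    cfg = SimCohortConfig(duration_pre=120, duration_post=120)
    a = synthesize_recording(p, cfg)
    b = synthesize_recording(p, cfg)
    assert np.array_equal(a.samples, b.samples)


def test_full_sync_bursts_all_cooccur():
    p = SubjectSimParams(sync_level=1.0, rng_seed=5)
    cfg = SimCohortConfig(duration_pre=600, duration_post=600)
    _, truth = synthesize_recording(p, cfg, return_truth=True)
    for seg in ("pre", "post"):
        frac = cooccurrence_fraction(truth["trains"][seg]["L"], truth["trains"][seg]["R"])
        assert frac == 1.0


def test_zero_sync_cooccurrence_at_chance_rate():
    """With independent hemispheres the co-occurrence fraction equals the
    closed-form chance rate of the renewal process: the probability of a
    burst onset in a 1-s window is its rate, 1/(dur_mean + ibi_mean)."""
    n_hits = 0
    n_bursts = 0
    for seed in range(8):
        p = SubjectSimParams(sync_level=0.0, rng_seed=100 + seed)
        cfg = SimCohortConfig(duration_pre=7200, duration_post=60)
        _, truth = synthesize_recording(p, cfg, return_truth=True)
        left, right = truth["trains"]["pre"]["L"], truth["trains"]["pre"]["R"]
        frac = cooccurrence_fraction(left, right)
        n = left[0].size
        n_hits += frac * n
        n_bursts += n
    chance = 1.0 / (p.burst_duration_mean + p.ibi_mean)
    emp = n_hits / n_bursts
    half_width = 1.96 * np.sqrt(emp * (1 - emp) / n_bursts)
    assert abs(emp - chance) <= half_width


def test_cooccurrence_monotone_in_sync_level():
    grid = [0.0, 0.25, 0.5, 0.75, 1.0]
    fracs = []
    for sync in grid:
        vals = []
        for seed in range(3):
            p = SubjectSimParams(sync_level=sync, rng_seed=200 + seed)
            cfg = SimCohortConfig(duration_pre=1800, duration_post=60)
            _, truth = synthesize_recording(p, cfg, return_truth=True)
            vals.append(
                cooccurrence_fraction(truth["trains"]["pre"]["L"], truth["trains"]["pre"]["R"])
            )
        fracs.append(np.mean(vals))
    assert all(b >= a for a, b in zip(fracs, fracs[1:]))


def test_burst_amplitude_conserved(short_recording_truth, fs):
    rec, truth = short_recording_truth
    target = truth["params"].baseline_amplitude
    for ch in ("F3", "P4"):
        pps = _burst_pp(rec.channel(ch), fs, truth["trains"]["pre"][ch])
        # each burst within +-15% of the requested peak-to-peak
        assert np.all(pps > 0.85 * target)
        assert np.all(pps < 1.15 * target)


def test_interburst_background_low(short_recording_truth, fs):
    rec, truth = short_recording_truth
    on, du = truth["trains"]["pre"]["F3"]
    x = rec.channel("F3")
    in_burst = np.zeros(x.size, bool)
    for o, d in zip(on, du):
        in_burst[int(o * fs) : int((o + d + 0.5) * fs)] = True
    ibi_pp = np.ptp(x[: int(600 * fs)][~in_burst[: int(600 * fs)]])
    assert ibi_pp <= 0.15 * truth["params"].baseline_amplitude


def test_no_drug_effect_is_amplitude_null():
    p = SubjectSimParams(drug_effect_slope=0.0, rng_seed=31)
    cfg = SimCohortConfig(duration_pre=600, duration_post=600)
    rec = synthesize_recording(p, cfg)
    x = rec.channel("P3")
    half = x.size // 2
    w = int(2 * FS)

    def mean_pp(seg):
        n = seg.size // w
        s = seg[: n * w].reshape(n, w)
        return (s.max(axis=1) - s.min(axis=1)).mean()

    pre, post = mean_pp(x[:half]), mean_pp(x[half:])
    assert abs(post - pre) / pre < 0.05


def test_drug_effect_scales_amplitude_and_sync():
    p = SubjectSimParams(drug_effect_slope=0.5, normalized_baseline=1.0, rng_seed=32)
    assert p.drug_factor == pytest.approx(0.5)
    cfg = SimCohortConfig(duration_pre=600, duration_post=600)
    rec, truth = synthesize_recording(p, cfg, return_truth=True)
    x = rec.channel("F4")
    half = x.size // 2
    assert np.ptp(x[half:]) < 0.75 * np.ptp(x[:half])


def test_too_short_segment_rejected():
    p = SubjectSimParams()
    with pytest.raises(ValueError, match="burst"):
        synthesize_recording(p, SimCohortConfig(duration_pre=5, duration_post=600))


@pytest.mark.parametrize(
    "kwargs",
    [
        {"sync_level": 1.2},
        {"ibi_mean": -1.0},
        {"burst_rate": 20.0},  # inconsistent with 3 s + 6 s cycle
        {"artifact_spec": [("bogus", 10.0, 5.0)]},
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        SubjectSimParams(**kwargs)


def test_cohort_reproducible_and_truth_table():
    cfg = SimCohortConfig(n_subjects=6, duration_pre=90, duration_post=90, rng_seed=9)
    het = CohortHeterogeneity(drug_effect_slope=0.5, artifact_rate_per_recording=0.0)
    recs_a, truth_a = synthesize_cohort(cfg, het)
    recs_b, truth_b = synthesize_cohort(cfg, het)
    assert all(np.array_equal(a.samples, b.samples) for a, b in zip(recs_a, recs_b))
    assert truth_a.equals(truth_b)
    assert set(truth_a.columns) >= {
        "subject_id", "baseline_amplitude", "sync_level", "drug_effect_slope",
        "gestational_age_days", "fentanyl", "diagnosis_group", "seed",
    }


def test_ground_truth_delta_anticorrelated_with_baseline():
    """With a constant positive slope, the construction-level drug effect is
    more negative for higher-baseline subjects (Spearman <= -0.8 on the
    ground-truth table, before any EEG is processed)."""
    cfg = SimCohortConfig(n_subjects=21, duration_pre=90, duration_post=90, rng_seed=4)
    _, truth = draw_cohort_params(cfg, CohortHeterogeneity(drug_effect_slope=0.5))
    rho = ss.spearmanr(truth["baseline_amplitude"], truth["true_delta_amplitude"]).statistic
    assert rho <= -0.8


def test_heterogeneity_spans_amplitude_range():
    cfg = SimCohortConfig(n_subjects=21, duration_pre=120, duration_post=120, rng_seed=2)
    het = CohortHeterogeneity(artifact_rate_per_recording=0.0)
    params, truth = draw_cohort_params(cfg, het)
    w = int(2 * FS)
    realized = []
    for p in params[:21]:
        rec = synthesize_recording(p, cfg)
        x = rec.channel("F3")
        n = x.size // w
        segs = x[: n * w].reshape(n, w)
        pp = segs.max(axis=1) - segs.min(axis=1)
        # mean of the top quartile approximates the burst amplitude
        realized.append(np.mean(np.sort(pp)[-n // 4 :]))
    assert max(realized) / min(realized) >= 3.0


def test_degenerate_heterogeneity_warns():
    with pytest.warns(UserWarning, match="degenerate"):
        CohortHeterogeneity(baseline_amplitude_range=(50.0, 50.0))
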