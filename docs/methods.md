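# Methods

## Scope and assumptions

The package quantifies the short-term effect of a sedative on newborn
cortical activity from a 4-channel EEG montage (F3, F4, P3, P4, common
midline reference, nominally 250 Hz). The analysis assumes: (i) the
recording is continuous across the administration timestamp and covers at
least 13 min before and 11 min after it; (ii) signals are already
referential — no re-referencing is performed, bipolar derivations are
sample-wise differences; (iii) the drug effect of interest is a step
contrast between a pre-drug baseline and a post-drug window, not a
pharmacokinetic time course. All timing is in seconds from recording start
with half-open intervals [t0, t1).

## Features

**rEEG.** Peak-to-peak amplitude per non-overlapping 2-s window, in µV.
Windows are anchored at t = 0; a trailing partial window is dropped. A
centered running mean over k = 5 windows (10 s, shrinking at the edges) is
provided for display only; raw window values always feed statistics. rEEG is
invariant to signal negation and constant offsets, and is checked exactly
against a brute-force per-window scan.

**ASI.** The synchrony measure is defined here as an
envelope-mutual-information statistic normalised by a circular-shift
surrogate null: (1) 1-s RMS envelopes of both signals over valid data;
(2) rank-based quantisation of each envelope into `n_bins = 4`
equal-occupancy levels — rank binning makes the statistic exactly invariant
to monotone amplitude rescaling of either channel; (3) plug-in
joint-histogram mutual information I₀ at zero lag; (4) a null of
`n_surrogates = 100` mutual-information values from circularly shifting one
quantised envelope by a uniform random shift of at least `min_shift = 30 s`;
(5) `ASI = log₂(I₀ / median(surrogates))`, with a floor of 1e-6 bits on both
terms of the ratio. Identical channels give I₀ = log₂(4) = 2 bits exactly;
independent channels give ASI ≈ 0 with the surrogate threshold rejecting at
its nominal rate. Degenerate (zero-variance) envelopes and segments with
less than 50% valid data return a missing value. The constants live in
`ASIParams`; they are this package's definition choices for a measure whose
published descriptions leave the instantiation open, selected so the
statistic has an exact self-information ceiling, exact rescaling invariance,
and a calibrated null.

## Preprocessing

Band-pass 0.2–35 Hz as a cascade of 4th-order Butterworth high- and
low-pass sections applied forward-backward (zero phase); attenuation one
octave outside the band exceeds 20 dB. Artifact detection runs per
derivation on the filtered signal over the same 2-s grid as rEEG, with three
detectors: amplitude (any |x| > 500 µV), high-frequency (25–35 Hz power
ratio > 0.5 of total), low-frequency (0.2–0.5 Hz power ratio > 0.9,
band components obtained with zero-phase filters so 2-s segments can be
scored despite the coarse spectral resolution of such short windows).
Flagged segments plus one guard segment on each side are excluded; removal
is by exclusion, never interpolation, because interpolation would fabricate
the amplitude structure rEEG measures. Thresholds are conventional neonatal
values and are exposed in `ArtifactConfig` rather than hard-coded. An epoch
with under 50% valid segments is missing.

## Trend designs

Long-term: features per 2.5-min epoch across the whole recording
(nominally 2 h on each side of administration, 96 epochs over 4 h),
per-subject trends plus the cohort mean, aligned at the drug timestamp.

Short-term: baseline = [drug − 13 min, drug − 1 min), post =
[drug + 1 min, drug + 11 min). The 1-min gaps absorb timestamp
uncertainty; the 12-min baseline (versus 10 min post) gives artifact-prone
pre-drug data more room. Each window is tiled into 2.5-min epochs from its
start; incomplete trailing epochs are dropped (12 min / 2.5 min → 4 epochs,
the 2 min nearest the gap unused — `anchor="end"` is available to keep the
epochs flush with the gap instead). Per side, the median over epoch values
is taken (a config flag allows pooling raw 2-s windows instead);
`delta = post_median − baseline_median`.

## Statistics

Two-sided nonparametric tests on an a-priori comparison plan (rEEG:
biparietal P3-P4, interfrontal F3-F4, four referential channels; ASI:
interhemispheric F3-P3 vs F4-P4, the two intrahemispheric pairs, frontal
F3 vs F4; clinical factors against the primary derivations P3-P4 and
interhemispheric). No multiplicity correction is applied — the family is
minimised up front — but every output row records the family size.
Spearman p-values are exact by full permutation enumeration for n ≤ 8 and
seeded Monte-Carlo permutation (20 000 draws) for n ≤ 12; the exhaustive
bound stops at 8 because 12! ≈ 4.8×10⁸ permutations is not enumerable at
interactive scale, and the Monte-Carlo null is indistinguishable from exact
at the resolution used. Rank-sum p-values are exact up to combined n = 20
(direct enumeration when ties are present); Kruskal–Wallis uses the
tie-corrected H with the χ² approximation. Missing subjects are dropped
listwise. Comparisons with too few subjects are reported as not-computed,
never silently skipped.

## Synthetic cohort generator

The generator emulates exactly the structure the features measure, with
every parameter recorded as ground truth:

* **Burst timing** — renewal process; burst durations lognormal
  (mean 3 s, σ = 0.35 log-units) and interburst intervals lognormal
  (mean 6 s, σ = 0.5 log-units), i.e. ≈ 6.7 bursts/min. The defaults are
  conventions for discontinuous neonatal EEG, not calibrations to any
  patient dataset.
* **Burst waveform** — 1–20 Hz band-limited noise under a half-sine
  envelope, rescaled per burst so the realised peak-to-peak matches the
  subject's baseline amplitude within ±5% jitter; overlapping bursts are
  pruned when trains are merged so amplitude is conserved. Interburst
  background is 10% of the burst amplitude peak-to-peak.
* **Synchrony** — each left-hemisphere burst is shared with the right with
  probability `sync_level` (onset jitter ≤ 0.2 s); unshared bursts are
  replaced from an independent train thinned to keep rates equal. At
  `sync_level = 0` the cross-hemisphere co-occurrence fraction has the
  closed form `burst_rate × window` (one onset per 1-s matching window at
  most), against which the generator is tested; at 1 it is exactly 1. Within a hemisphere, frontal and parietal channels share bursts
  with fixed probability 0.9.
* **Drug effect** — an instantaneous step at the timestamp: burst amplitude
  and sync_level are both multiplied by `max(0, 1 − slope × b)`, where `b`
  is the subject's baseline amplitude normalised to the cohort maximum.
  This builds in the baseline-proportional effect the analysis is designed
  to detect; slope 0 is an exact null.
* **Artifacts** — three injectable classes: ±1200 µV square excursions,
  sustained 30 Hz oscillation (80 µV), 0.25 Hz drift (500 µV peak-to-peak),
  each with channel-specific phase so bipolar derivations do not cancel.
* **Cohort** — 21 subjects by default; baseline amplitudes uniform in
  25–150 µV, sync levels in 0.4–0.9, gestational age 27–42 weeks, 12/21 on
  fentanyl, diagnosis groups sized 5/8/6/2; on average two artifacts per
  recording. All draws descend from one `SeedSequence`, so a cohort is
  bit-identical under a fixed seed.

What the generator does **not** emulate: realistic spectra, sleep-state
cycling, age-dependent maturation of the background, non-stationary artifact
statistics, or inter-channel volume conduction. Passing tests therefore
demonstrate that the pipeline recovers the constructs it defines (amplitude
level, burst co-occurrence, baseline-proportional change) — not clinical
validity on patient data.

## Numerical and implementation choices

* EDF files are written by a minimal built-in EDF+C writer (16-bit, fixed
  0.1 µV/bit gain over ±3276.8 µV, 1-s records, annotations channel carrying
  the `DEX` timestamp) and read through MNE; round-trip error is bounded by
  one quantisation step.
* Channel labels are normalised case-insensitively, tolerating `EEG `
  prefixes and `-Fz/-Cz/-ref` suffixes.
* A recording that cannot host the short-term design is excluded with a
  logged reason; a sampling rate other than 250 Hz warns and proceeds, since
  every definition is in seconds.
* Validation problem sizes: oracle equivalence on 20 ten-minute signals;
  ASI null calibration on 200 ten-minute noise pairs; synchrony
  monotonicity over a 5-point sync grid × 10 seeds; detector performance on
  20 twenty-minute fixtures; effect recovery on 50 cohorts of 21 subjects
  per slope, generated at drug-proximal length (14 min pre / 12 min post,
  the span the short-term design consumes) with the full
  filter–mask–epoch–median pipeline in the loop.

## Known limitations

* The ASI instantiation is one defensible member of a family; absolute ASI
  values are not comparable across different envelope/quantisation choices.
* Artifact thresholds are fixed conventions; recordings with systematically
  different noise floors may need `ArtifactConfig` adjustments.
* The short-term design assumes the annotated administration time is within
  ±1 min of the true one; larger errors bias the contrast toward zero.
* The statistics layer implements only the planned comparisons; it is not a
  general modelling framework (no regression, no mixed effects).
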