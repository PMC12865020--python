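# Methods

This note documents the models, parameter choices and numerical decisions
behind `tepkit`, and what the synthetic-data experiments do and do not
demonstrate about real recordings.

## Signal model of the synthetic session

A session follows the factorial design: 2 cortical targets (M1, SMA) × 4
sham conditions × (140 real + 140 sham) randomly interleaved trials per
block, inter-stimulus interval 2.5 s with ±0.5 s uniform jitter, 64
channels (10-10 subset, positions from the bundled standard montage) at
5 kHz, epochs −1500..1500 ms around the pulse. Every trial is a sum of:

* **TEP components** (real trials only): Gaussian bumps in time (latency
  = mean, width = SD) with 2D-Gaussian scalp topographies normalized to
  unit peak. Defaults — M1: P30 (+2.5 µV, C3), N45 (−3 µV, C3), P60
  (+2 µV, FC3), P120 (+2 µV, C3); SMA: P25 (+2 µV, C3), N40 (−2 µV,
  P5), P55 (+3 µV, FCz). Latencies and signs follow the component
  nomenclature; amplitudes are in the low-µV range typical of
  sham-subtracted TEPs. The temporal shape is a modeling convenience:
  real deflections are asymmetric, but nothing downstream depends on the
  shape beyond smoothness.
* **PEP complex** (all trials): frontocentral N100/P200/N300 bumps with
  a common FCz-centered topography, scaled by a saturating response
  curve plus a fixed auditory share (default 3 µV, identical in real and
  sham — the sham coil click matches the real click). The relative bump
  amplitudes are normalized so that scale 1 produces exactly 1 µV of the
  calibration estimator's peak-to-peak measure (max [170, 230) − min
  [280, 350) ms at FCz); the curve's output is therefore directly the
  estimator's expected value.
* **PEP response curve**: Hill form `a·I^h/(I^h + i_half^h)` with a_max
  = 20 µV, i_half = 100%, h = 4. The functional form is a design choice
  (only the saturation point is empirically anchored); these constants
  put saturation at 98.8% of the asymptote at I = 300% of the perception
  threshold and make the 300%→600% step change the PEP by 0.23 µV —
  i.e. below the ±0.5 µV calibration tolerance, which is what "PEP
  saturation" operationally means. a_max = 20 µV matches the large
  frontocentral PEPs elicited by strong somatosensory input and gives
  the curve enough slope at mid-intensities (~0.07 µV per percentage
  point at 150%) for a ±0.5 µV amplitude tolerance to pin the intensity
  to within ~5%.
* **Decay artifact** (all trials): per-channel `a·exp(b·t)` for t ≥ 0,
  defaults a = 40 µV, b = −50 s⁻¹ (time constant 20 ms, confining the
  artifact to the first tens of milliseconds). It is present in sham
  trials too: the artifact originates from the scalp electric
  stimulation and coil discharge, which the sham shares. This matters —
  see "Known limitations".
* **Pulse artifact**: a damped 300 Hz oscillation (default 500 µV)
  confined to −5..20 ms, identical across trials.
* **Noise**: per-channel mixture of 1/f-amplitude and white noise
  (default 3 µV RMS, 60% pink). Spatial correlation is not modeled.
* **Subject variability**: one multiplicative gain per subject (SD 0.2)
  on all evoked content. MEP contamination is a per-trial flag drawn at
  5.8% of real-TMS trials (plus an optional re-afferent bump, off by
  default).

All randomness derives from one master seed via per-subject
`SeedSequence` streams; identical seeds give bit-identical sessions.

The parcel-space stand-in (`simulate_parcels`) mixes sensor signals
through a fixed, spatially local Gaussian sensor→parcel projection onto
290 pseudo-randomly placed parcels with a symmetrized k-nearest-neighbor
adjacency. It reproduces the *statistical interface* of source-space
analyses (parcels as "channels" with a neighbor graph), not the physics
of volume conduction or inverse modeling, which are out of scope.

## Preprocessing

Fixed order: epoch → baseline (−500..−25 ms) → decay fit/subtraction →
pulse-window interpolation (−5..20 ms) → downsample (5 kHz → 1 kHz) →
rejection. Windows are closed at the lower edge, open at the upper edge;
times are ms relative to the pulse.

**Decay fit.** Weighted least squares of `a·exp(b·t)` over 15–500 ms,
weights linearly spaced 100→1 multiplying the squared residuals
(standard WLS semantics), independent variable in seconds. The amplitude
is profiled out in closed form, leaving a bounded scalar minimization
over b — deterministic, no starting-point sensitivity. The rate is
constrained to b ∈ [−200, 0) s⁻¹ (time constant ≥ 5 ms): faster decays
are indistinguishable from the residual pulse artifact that the
interpolation step removes anyway, and allowing them lets the optimizer
chase single samples at the window edge with explosive backward
extrapolation toward t = 0. The fitted curve is subtracted from all
post-pulse samples (pre-pulse samples untouched); the exponential form
guarantees bounded extrapolation beyond 500 ms.

**Pulse-window interpolation.** A degree-3 polynomial is least-squares
fit to 10 flanking samples on each side of the excised window and
evaluated across it. This reproduces any cubic (and hence linear) input
exactly; a natural spline would not (its end conditions force zero
curvature).

**Downsampling.** Zero-phase 8th-order Butterworth low-pass at 0.4× the
target Nyquist, then decimation by the integer factor; kept samples are
every factor-th sample from the first, so output length is ⌈n/q⌉.

**Rejection.** An automated, deterministic surrogate for visual
inspection: robust z-scores (median/MAD) of per-channel median
peak-to-peak amplitude, then of per-trial maximum peak-to-peak over the
surviving channels, threshold 5; all MEP-flagged trials are dropped.

## PEP estimation and intensity calibration

The estimator averages 30 trials after skipping the first 10 (stimulus
habituation), baseline-corrects when the epoch covers the baseline
window, and takes max [170, 230) − min [280, 350) ms at FCz. The late
P200–N300 complex is used rather than the N100 because genuine TEP
components overlap the N100; calibrating on it would over-correct.

The titration replaces a manual 10–15 min procedure with exponential
bracketing (doubling the upper intensity until the target is enclosed,
capped at 1600%) followed by bisection, requesting 40 fresh sham trials
per evaluation with fixed per-call seeds. It stops when the measured PEP
is within ±0.5 µV of the target; a target above the response asymptote
is reported as unreachable (saturation diagnosis) rather than iterated
forever.

## Cluster-based permutation statistics

Pointwise dependent-samples t (or repeated-measures F) maps over nodes ×
time are thresholded at the two-sided α = 0.05 quantile of the
parametric reference distribution (upper-tail for F), clustered under
combined spatial (neighbor graph) + temporal (consecutive samples)
adjacency, and summarized by the sum of the statistic (cluster mass;
size and max are available). The null distribution of the maximum
absolute cluster mass is built from 1000 permutations by default —
sign-flipping subject difference maps for t, permuting condition labels
within subject for F — and Monte-Carlo p = (b + 1)/(P + 1), so p-values
are bounded below by 1/(P + 1). The minimum-neighbor rule (default 3 for
parcel spaces, 0 for sensors) prunes suprathreshold points with too few
simultaneously suprathreshold spatial neighbors before clustering,
applied once per map. The two-stage procedure extracts significant time
windows from the full spatiotemporal test, averages each subject's maps
within each window, and reruns a spatial-only cluster test (pairwise
post-hoc t-tests after a significant ANOVA). Degenerate 0/0 statistic
points (identical conditions) are set to zero explicitly, with a
relative tolerance guarding against float residue masquerading as
effects.

## Bootstrap ROPE equivalence

Subjects are resampled with replacement jointly across conditions
(preserving the repeated-measures pairing — resampling independently per
condition would destroy the subject effect that dominates evoked
amplitudes). Per resample: per-condition means, all pairwise
differences, and the pairwise-pooled SD (√ of the mean of the two
conditions' variances). A resample counts as inside the ROPE when
|difference| ≤ 0.4 × its pooled SD; coverage is the fraction of 10,000
resamples inside, and equivalence is declared per pair iff coverage
strictly exceeds 97.5%. The summary p for a comparison family is the
worst per-pair p (= 1 − coverage). The Cohen's-d threshold 0.4 is used
as stated rather than the looser "half a standard deviation" gloss. The
time-course form applies the same machinery per sample over 20–300 ms
(one shared set of subject resamples per bootstrap iteration) and
reports contiguous runs where all pairs are equivalent.

**Operating characteristics.** The windowed-amplitude experiments fix
n = 20 subjects, within-condition noise SD 1, and between-subject SD 4
(`simulate_amplitude_table` defaults). The 4:1 ratio reflects that
trial-averaged evoked amplitudes vary far more across subjects than
across conditions within a subject; it was chosen by a design simulation
over candidate ratios and gives a ~97% equivalence rate under a true
null and ~0% at a true d = 1.0. With between-subject variability
comparable to the within-subject noise the ROPE shrinks toward the
bootstrap's own sampling error and the test loses its ability to declare
equivalence at n = 20 — a real limitation of d-scaled ROPEs, visible in
near-zero-variance time samples.

## What the synthetic experiments show — and don't

Passing tests demonstrate that each stage does what it claims on data
with known ground truth: trial bookkeeping matches the design
arithmetic; decay parameters are recovered exactly (noiseless) and to
2.7% median error at 5 µV noise; the sham subtraction returns the exact
TEP template when PEPs match and flags late-band residuals when they do
not; cluster tests hold the family-wise error at ≈0.05 under the null
and detect d = 2 patches with ≥80% coverage; the equivalence test
declares true nulls equivalent ≥80% of the time and true d = 1 effects
almost never. They do **not** demonstrate performance under real-data
features that the generator omits: non-Gaussian and spatially correlated
noise, ocular/muscle artifacts, electrode drift, non-exponential decay
shapes, evoked-latency jitter, or inverse-modeling errors in true source
space. The subspace-suppression and ocular-cleaning steps used on real
recordings are deliberate hook points, not implemented here.

## Known limitations

* **The decay fit absorbs evoked content.** Any implementation of
  per-trial exponential subtraction (including the original) removes the
  component of the evoked response that resembles `a·exp(b·t)` over the
  fit window. For the large frontocentral PEP complex this absorption
  reaches ~0.4–1 µV RMS per trial. Because real and sham trials share
  the PEP and the artifact, the distortion cancels in the real-minus-
  sham contrast (measured residual 0.055 µV RMS on the TEP estimate);
  decay-removal *fidelity* is therefore quantified on content that does
  not mimic the artifact (TEP-only configuration), and the cancellation
  is tested separately. Analyses that consume un-subtracted single
  conditions (not TEP contrasts) should expect PEP-band bias.
* **Calibration assumes a stationary PEP.** A session-long drift in PEP
  amplitude defeats a one-shot calibration (demonstrated as a property
  test); the package does not implement re-calibration schedules.
* **The parcel space is a statistical stand-in**, not a forward model;
  parcel-level conclusions transfer to real source estimates only to the
  extent that the neighbor-graph interface is what matters.
* Scaled-down problem sizes are used throughout the test-suite and
  analysis scripts (e.g. 6-node graphs, 300–400 Monte-Carlo repetitions,
  500-permutation nulls, 2000-resample bootstraps); these sizes give the
  binomial confidence the assertions need while keeping each experiment
  in the seconds-to-minutes range.
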