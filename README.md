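# tepkit

Sham-controlled TMS–EEG analysis in Python: isolate TMS-evoked potentials
(TEPs) from the peripherally evoked potentials (PEPs) that contaminate
them, with the statistics needed to claim both differences and
equivalence between conditions.

## The problem

A TMS pulse excites cortex directly, but it also clicks and twitches the
scalp. The EEG response is therefore a superposition of the TEP (the
signal of interest) and a multimodal sensory response — the PEP, a large
frontocentral N100/P200 complex. A sham condition that reproduces the
sensory experience without cortical stimulation lets the PEP be measured
on its own and subtracted:

```
TEP(t) = mean[real trials](t) − mean[sham trials](t)
```

which is valid only if the sham PEP actually matches the real-TMS PEP.
Two matching strategies are implemented: **PEP saturation** (drive the
somatosensory input so hard — ≥300% of the perception threshold — that
the PEP amplitude is at ceiling in both conditions) and **calibrated
matching** (titrate the sham electric-stimulation intensity until the
sham PEP equals the real-TMS PEP within ±0.5 µV, measured as the FCz
peak-to-peak amplitude max[170, 230) ms − min[280, 350) ms on the average
of 30 trials after a 10-trial habituation skip).

Around that core the package provides:

* **`tepkit.simulate`** — a synthetic session generator with the full
  factorial design (2 cortical targets × 4 sham conditions × 140 real +
  140 sham trials, ISI 2.5 ± 0.5 s, 64 channels at 5 kHz), Gaussian-bump
  TEP components with scalp topographies, a saturating (Hill) PEP
  response curve, exponential decay and pulse artifacts, 1/f + white
  noise, and MEP-contaminated trials. Every downstream stage is testable
  against known ground truth.
* **`tepkit.preprocess`** — baseline correction (−500..−25 ms), weighted
  least-squares fit and subtraction of the decay artifact `a·exp(b·t)`
  (fit over 15–500 ms, weights 100→1), cubic interpolation of the −5..20
  ms pulse window, anti-aliased downsampling 5 kHz → 1 kHz, and automated
  channel/trial rejection.
* **`tepkit.calibration`** — the PEP estimator and the deterministic
  bracketing/bisection intensity-titration loop, plus the 300%-vs-600%
  saturation check.
* **`tepkit.evoked`** — condition averaging, sham subtraction, per-trial
  z-standardization for parcel-space analyses.
* **`tepkit.cluster`** — cluster-based permutation statistics over
  channels/parcels × time: dependent-samples t (sign-flip null) and
  repeated-measures ANOVA (within-subject label permutation), custom
  neighbor graphs with a minimum-neighbor rule for parcel spaces, and the
  two-stage window→channel procedure.
* **`tepkit.equivalence`** — bootstrap ROPE equivalence testing: subjects
  resampled with replacement, pairwise mean differences compared against
  ±0.4 × pooled SD (Cohen's d scale), equivalence declared when >97.5%
  of the bootstrap distribution lies inside the ROPE; windowed
  (30–50/50–80/80–120/120–200 ms) and whole-time-course forms.

## Worked example

Calibrate a sham intensity against a simulated session
(`analysis/03_pimsic_calibration.py`):

```text
Calibration converged in 7 measurements at 143.8% of the perception
threshold (target 19.89 µV, achieved 19.70 µV). Doubling 300% -> 600%
changes the PEP by 0.06 µV: saturated regime.
```

The generator's real-TMS PEP corresponds to an effective somatosensory
intensity of 150%; the loop recovers 143.8% (4% off, within the ±0.5 µV
amplitude tolerance), and the saturation check confirms the response
ceiling: doubling a 300%-threshold stimulus moves the PEP by only 0.06
µV.

The full analysis sequence lives in `analysis/` and writes its tables to
`results/`:

1. `01_design_check.py` — session arithmetic (8 blocks × 280 trials =
   2240; mean ISI 2.502 s in [2.0, 3.0] s).
2. `02_decay_removal.py` — decay fits recover (a, b) exactly without
   noise and with 2.7% median error at 5 µV noise; removing a 40 µV
   artifact leaves the underlying signal within 0.06 µV RMS.
3. `03_pimsic_calibration.py` — the example above.
4. `04_tep_isolation.py` — end-to-end preprocessing and sham
   subtraction; a 20% miscalibrated sham PEP shows up as a late
   (100–300 ms) residual.
5. `05_cluster_stats.py` — the two-stage cluster ANOVA localizes an
   injected condition-4 deflection to a 148–244 ms window (post-hoc
   pairwise p ≈ 0.002–0.009) while holding the family-wise error at
   0.05 under the null.
6. `06_equivalence.py` — with no true condition differences, all 24
   window × pair comparisons are declared equivalent; a 2 µV deflection
   at 200 ms is excluded from the time-course equivalence intervals
   while early components remain equivalent.

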