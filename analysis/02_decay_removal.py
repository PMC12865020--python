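"""Characterize the weighted exponential decay-artifact removal.

Two experiments:
  1. parameter recovery of a*exp(b*t) over 200 random artifacts, noiseless
     and at 5 µV white noise;
  2. recovery of the underlying evoked signal when the default decay
     artifact is added to a noiseless TEP-only epoch, plus the distortion
     the fit itself induces on artifact-free data.

Writes results/decay_recovery.csv.
"""

import numpy as np
import pandas as pd

from tepkit.preprocess import baseline_correct, fit_decay, subtract_decay
from tepkit.simulate import (
    DecayParams,
    PEPResponseCurve,
    SessionDesign,
    simulate_session,
)

CHANNELS = ["FCz", "C3", "FC3", "Cz", "C1", "CP1", "F3", "P3"]


def recovery_experiment(n_cases=200, noise_uv=0.0, seed=0):
    t = np.arange(0.015, 0.5, 1 / 5000)
    rng = np.random.default_rng(seed)
    errs = []
    for _ in range(n_cases):
        a, b = rng.uniform(5, 80), rng.uniform(-40, -5)
        y = a * np.exp(b * t) + noise_uv * rng.standard_normal(t.size)
        f = fit_decay(y, t)
        errs.append(max(abs(f.a - a) / a, abs(f.b - b) / abs(b)))
    return np.asarray(errs)


def signal_recovery():
    design = SessionDesign(
        targets=("M1",), trials_per_cell=1, n_subjects=1,
        sampling_rate=1000.0, epoch_window_ms=(-600.0, 600.0),
        n_channels=8, seed=4,
    )
    kw = dict(noise_level=0.0, pulse_artifact_uv=0.0, subject_amp_sd=0.0,
              auditory_pep_uv=0.0, pep_curve=PEPResponseCurve(a_max=1e-9),
              decay=DecayParams(a=0.0, b=-50.0))
    clean = baseline_correct(simulate_session(design, channels=CHANNELS, **kw)[0])
    kw["decay"] = DecayParams(a=40.0, b=-50.0)
    dirty = baseline_correct(simulate_session(design, channels=CHANNELS, **kw)[0])
    out, _ = subtract_decay(dirty)
    m = (out.times >= 30) & (out.times < 500)
    resid = np.sqrt(((out.data[:, :, m] - clean.data[:, :, m]) ** 2).mean())
    noop, _ = subtract_decay(clean)
    noop_rms = np.sqrt(((noop.data - clean.data) ** 2).mean())
    return resid, noop_rms


def main() -> None:
    e0 = recovery_experiment(noise_uv=0.0, seed=0)
    e5 = recovery_experiment(noise_uv=5.0, seed=1)
    resid, noop = signal_recovery()
    rows = pd.DataFrame(
        [
            ("median_rel_error_noiseless", float(np.median(e0))),
            ("max_rel_error_noiseless", float(e0.max())),
            ("median_rel_error_5uV", float(np.median(e5))),
            ("p90_rel_error_5uV", float(np.percentile(e5, 90))),
            ("signal_recovery_rms_uV", float(resid)),
            ("noop_distortion_rms_uV", float(noop)),
        ],
        columns=["quantity", "value"],
    )
    rows.to_csv("results/decay_recovery.csv", index=False)
    print(rows.to_string(index=False))
    print(f"\nNoiseless fits are exact to {np.median(e0):.2e} relative error; "
          f"at 5 µV noise the median error is {np.median(e5)*100:.1f}%. "
          f"Removing a 40 µV default artifact leaves the underlying signal "
          f"within {resid:.3f} µV RMS (30-500 ms).")


if __name__ == "__main__":
    main()
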