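"""Run the sham stimulus-intensity calibration loop against the generator.

Measures the real-TMS PEP (peak-to-peak of the FCz average, max over
170-230 ms minus min over 280-350 ms, 30 of 40 trials after a 10-trial
habituation skip), titrates the sham ES intensity until the sham PEP
matches it within +/-0.5 µV, and checks the 300% vs 600% saturation
property of the response curve. Writes results/calibration.json.
"""

import json

from tepkit.calibration import calibrate_intensity, estimate_pep, saturation_check
from tepkit.simulate import (
    DecayParams,
    PEPResponseCurve,
    SessionDesign,
    ShamCondition,
    simulate_session,
)

CHANNELS = ["FCz", "C3", "FC3", "Cz", "C1", "CP1", "F3", "P3"]
CURVE = PEPResponseCurve()
NOISE_UV = 1.0  # residual noise after online averaging of the monitor signal


def sham_source(intensity, seed):
    design = SessionDesign(
        targets=("M1",),
        conditions=(ShamCondition("cal", "scalp", "fixed", float(intensity),
                                  False),),
        trials_per_cell=40, n_subjects=1, sampling_rate=1000.0,
        epoch_window_ms=(-600.0, 600.0), n_channels=8, mep_rate=0.0,
        seed=seed,
    )
    es = simulate_session(
        design, pep_curve=CURVE, channels=CHANNELS, noise_level=NOISE_UV,
        pulse_artifact_uv=0.0, subject_amp_sd=0.0,
        decay=DecayParams(a=0.0, b=-50.0),
    )[0]
    return es.select((es.trial_table["stim_type"] == "sham").to_numpy())


def main() -> None:
    # the real-TMS PEP to match: the generator's effective somatosensory
    # intensity for real TMS is 150% of the perception threshold
    target = estimate_pep(sham_source(150.0, 424242)).amplitude
    res = calibrate_intensity(target, sham_source, seed=11)
    sat = saturation_check(sham_source, seed=99)

    out = {
        "target_pep_uv": round(target, 3),
        "calibrated_intensity_pct": round(res.intensity, 2),
        "achieved_pep_uv": round(res.achieved_pep, 3),
        "error_uv": round(abs(res.achieved_pep - target), 3),
        "iterations": res.iterations,
        "converged": res.converged,
        "history": [[round(i, 2), round(a, 3)] for i, a in res.history],
        "saturation_check": {
            "amplitude_300pct_uv": round(sat["amplitudes"][0], 3),
            "amplitude_600pct_uv": round(sat["amplitudes"][1], 3),
            "difference_uv": round(sat["difference"], 3),
            "saturated": sat["saturated"],
        },
    }
    with open("results/calibration.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(json.dumps(out, indent=2))
    print(f"\nCalibration converged in {res.iterations} measurements at "
          f"{res.intensity:.1f}% of the perception threshold "
          f"(target {target:.2f} µV, achieved {res.achieved_pep:.2f} µV). "
          f"Doubling 300% -> 600% changes the PEP by "
          f"{sat['difference']:.2f} µV: saturated regime.")


if __name__ == "__main__":
    main()
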