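"""Isolate TEPs by sham subtraction after full preprocessing.

Simulates a small multi-subject session (noise, decay and pulse artifacts
on), runs the cleaning chain (baseline -> decay fit/subtraction -> pulse
interpolation -> downsampling -> rejection), averages real and sham trials
per condition, and subtracts. Reports how close the recovered TEP is to
the generating template, and the late-band residual when the sham PEP is
deliberately miscalibrated by 20% (the mismatch signature).

Writes results/tep_isolation.csv.
"""

import numpy as np
import pandas as pd

from tepkit.evoked import average_condition, subtract_sham
from tepkit.preprocess import PreprocParams, preprocess
from tepkit.simulate import (
    SessionDesign,
    default_tep_components,
    evaluate_templates,
    simulate_session,
)

CHANNELS = ["FCz", "C3", "FC3", "Cz", "C1", "CP1", "F3", "P3"]
N_SUBJECTS = 4
TRIALS_PER_CELL = 10  # scaled-down session; statistics scripts go wider


def run_condition(pep_mismatch: float) -> pd.DataFrame:
    design = SessionDesign(
        targets=("M1",), trials_per_cell=TRIALS_PER_CELL,
        n_subjects=N_SUBJECTS, sampling_rate=5000.0,
        epoch_window_ms=(-600.0, 600.0), n_channels=8, seed=77,
    )
    sessions = simulate_session(design, channels=CHANNELS, noise_level=2.0,
                                pep_mismatch=pep_mismatch)
    params = PreprocParams()
    rows = []
    for subj, es in enumerate(sessions):
        clean, log = preprocess(es, params)
        template = evaluate_templates(
            default_tep_components(clean.channel_names, ("M1",))["M1"],
            clean.times,
        )
        for cond in ("cond1", "cond2", "cond3", "cond4"):
            real = average_condition(clean, condition=cond, stim_type="real")
            sham = average_condition(clean, condition=cond, stim_type="sham")
            tep = subtract_sham(real, sham)
            m = (tep.times >= 30) & (tep.times < 300)
            late = (tep.times >= 100) & (tep.times < 300)
            err = tep.data - template
            rows.append({
                "subject": subj,
                "condition": cond,
                "pep_mismatch": pep_mismatch,
                "n_rejected_trials": len(log.excluded_trials),
                "tep_rms_error_uV": float(np.sqrt((err[:, m] ** 2).mean())),
                "late_band_energy": float((tep.data[:, late] ** 2).sum()),
            })
    return pd.DataFrame(rows)


def main() -> None:
    matched = run_condition(0.0)
    mismatched = run_condition(0.2)
    table = pd.concat([matched, mismatched], ignore_index=True)
    table.to_csv("results/tep_isolation.csv", index=False)

    err = matched["tep_rms_error_uV"].mean()
    e_match = matched["late_band_energy"].mean()
    e_mis = mismatched["late_band_energy"].mean()
    print(table.groupby(["pep_mismatch", "condition"])
          [["tep_rms_error_uV", "late_band_energy"]].mean().round(3))
    print(f"\nAcross {N_SUBJECTS} subjects the recovered TEP deviates from "
          f"the generating template by {err:.3f} µV RMS (30-300 ms). "
          f"A 20% sham-PEP excess raises late-band (100-300 ms) energy "
          f"{e_mis / e_match:.1f}-fold — the signature of a miscalibrated "
          f"sham.")


if __name__ == "__main__":
    main()
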