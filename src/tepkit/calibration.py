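"""PEP amplitude estimation and sham stimulus-intensity calibration.

The estimator averages 30 trials (after skipping the first 10 for
habituation) and takes the FCz peak-to-peak amplitude: the maximum over
[170, 230) ms minus the minimum over [280, 350) ms. The N100 is
deliberately excluded from this measure because genuine TMS-evoked
components overlap it; the later P200-N300 complex is a purer sensory
response.

The calibration loop titrates the sham electric-stimulation intensity
until the sham PEP matches a target amplitude within +/-0.5 µV, replacing
a manual titration with deterministic exponential bracketing followed by
bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .simulate import EpochSet

__all__ = [
    "PepEstimate",
    "CalibrationResult",
    "estimate_pep",
    "calibrate_intensity",
    "saturation_check",
]

PEAK_WINDOW_MS = (170.0, 230.0)
TROUGH_WINDOW_MS = (280.0, 350.0)


@dataclass(frozen=True)
class PepEstimate:
    amplitude: float  # µV, peak-to-peak
    peak_latency: float  # ms of the max in the peak window
    trough_latency: float  # ms of the min in the trough window
    n_trials_used: int
    reference_channel: str


@dataclass
class CalibrationResult:
    intensity: float  # % of perception threshold
    achieved_pep: float  # µV
    target_pep: float  # µV
    iterations: int
    converged: bool
    history: list[tuple[float, float]] = field(default_factory=list)
    diagnosis: str = ""


def estimate_pep(
    epochs: EpochSet,
    reference_channel: str = "FCz",
    skip_first: int = 10,
    use: int = 30,
    baseline_window_ms: tuple[float, float] | None = (-500.0, -25.0),
) -> PepEstimate:
    """Peak-to-peak PEP amplitude from the average of ``use`` trials.

    Trials are taken in chronological (storage) order after skipping the
    first ``skip_first``. Each trial is baseline-corrected before averaging
    when the baseline window is covered by the epoch; windows are closed at
    the lower edge and open at the upper edge, latencies reported on the
    sample grid.
    """
    needed = skip_first + use
    if epochs.n_trials < needed:
        raise ValueError(
            f"need at least {needed} trials (skip {skip_first} + use {use}), "
            f"got {epochs.n_trials}"
        )
    if reference_channel not in epochs.channel_names:
        raise ValueError(f"reference channel {reference_channel!r} not present")
    ci = epochs.channel_index(reference_channel)
    trials = epochs.data[skip_first : skip_first + use, ci, :]
    if baseline_window_ms is not None:
        bmask = (epochs.times >= baseline_window_ms[0]) & (
            epochs.times < baseline_window_ms[1]
        )
        if bmask.any():
            trials = trials - trials[:, bmask].mean(axis=1, keepdims=True)
    avg = trials.mean(axis=0)

    pmask = (epochs.times >= PEAK_WINDOW_MS[0]) & (epochs.times < PEAK_WINDOW_MS[1])
    tmask = (epochs.times >= TROUGH_WINDOW_MS[0]) & (epochs.times < TROUGH_WINDOW_MS[1])
    if not pmask.any() or not tmask.any():
        raise ValueError("epoch does not cover the 170-230 / 280-350 ms windows")
    ip = np.argmax(avg[pmask])
    it = np.argmin(avg[tmask])
    peak = avg[pmask][ip]
    trough = avg[tmask][it]
    return PepEstimate(
        amplitude=float(peak - trough),
        peak_latency=float(epochs.times[pmask][ip]),
        trough_latency=float(epochs.times[tmask][it]),
        n_trials_used=use,
        reference_channel=reference_channel,
    )


def _measure(
    trial_source: Callable[[float, int], EpochSet],
    intensity: float,
    seed: int,
    reference_channel: str,
    skip_first: int,
    use: int,
) -> float:
    epochs = trial_source(intensity, seed)
    return estimate_pep(
        epochs, reference_channel=reference_channel, skip_first=skip_first, use=use
    ).amplitude


def calibrate_intensity(
    target_pep: float,
    trial_source: Callable[[float, int], EpochSet],
    tolerance: float = 0.5,
    max_iter: int = 40,
    intensity_lo: float = 0.0,
    intensity_hi: float = 100.0,
    intensity_max: float = 1600.0,
    reference_channel: str = "FCz",
    skip_first: int = 10,
    use: int = 30,
    seed: int = 0,
) -> CalibrationResult:
    """Find the sham ES intensity whose PEP matches ``target_pep``.

    ``trial_source(intensity, seed)`` must return a fresh batch of sham
    trials (at least ``skip_first + use``), deterministic given its
    arguments; per-call seeds are fixed so the whole loop is reproducible.
    Strategy: double the upper bracket until the target is enclosed, then
    bisect; stop when the measured PEP is within ``tolerance`` of the
    target or ``max_iter`` evaluations are spent. A target above the
    response asymptote is reported as unreachable.
    """
    if target_pep < 0:
        raise ValueError("target_pep must be >= 0")
    history: list[tuple[float, float]] = []
    calls = 0

    def measure(i: float) -> float:
        nonlocal calls
        calls += 1
        amp = _measure(trial_source, i, seed + calls, reference_channel, skip_first, use)
        history.append((i, amp))
        return amp

    lo, hi = intensity_lo, intensity_hi
    amp_lo = measure(lo)
    if abs(amp_lo - target_pep) <= tolerance:
        return CalibrationResult(lo, amp_lo, target_pep, calls, True, history)
    if amp_lo > target_pep:
        # response at the search floor already exceeds the target
        return CalibrationResult(
            lo, amp_lo, target_pep, calls, False, history,
            diagnosis="target below response at minimum intensity",
        )
    amp_hi = measure(hi)
    while amp_hi < target_pep - tolerance and hi < intensity_max and calls < max_iter:
        lo, amp_lo = hi, amp_hi
        hi = min(2.0 * hi, intensity_max)
        amp_hi = measure(hi)
    if abs(amp_hi - target_pep) <= tolerance:
        return CalibrationResult(hi, amp_hi, target_pep, calls, True, history)
    if amp_hi < target_pep:
        return CalibrationResult(
            hi, amp_hi, target_pep, calls, False, history,
            diagnosis="target unreachable (saturation)",
        )
    # bracketed: amp_lo < target - tol, amp_hi > target + tol
    best_i, best_amp = (lo, amp_lo) if abs(amp_lo - target_pep) < abs(
        amp_hi - target_pep
    ) else (hi, amp_hi)
    while calls < max_iter:
        mid = 0.5 * (lo + hi)
        amp_mid = measure(mid)
        if abs(amp_mid - target_pep) < abs(best_amp - target_pep):
            best_i, best_amp = mid, amp_mid
        if abs(amp_mid - target_pep) <= tolerance:
            return CalibrationResult(mid, amp_mid, target_pep, calls, True, history)
        if amp_mid < target_pep:
            lo = mid
        else:
            hi = mid
    return CalibrationResult(
        best_i, best_amp, target_pep, calls, False, history,
        diagnosis=f"max_iter={max_iter} reached before |error| <= {tolerance}",
    )


def saturation_check(
    trial_source: Callable[[float, int], EpochSet],
    intensities: tuple[float, float] = (300.0, 600.0),
    tolerance: float = 0.5,
    reference_channel: str = "FCz",
    skip_first: int = 10,
    use: int = 30,
    seed: int = 0,
) -> dict:
    """Compare PEP amplitudes at two high intensities.

    In a saturating response regime, doubling the intensity (300% -> 600%
    of the perception threshold) should change the PEP by less than the
    calibration tolerance; the ``saturated`` flag records that.
    """
    if any(i < 0 for i in intensities):
        raise ValueError("intensities must be >= 0")
    amps = [
        _measure(trial_source, inten, seed + k + 1, reference_channel, skip_first, use)
        for k, inten in enumerate(intensities)
    ]
    diff = abs(amps[1] - amps[0])
    return {
        "intensities": tuple(intensities),
        "amplitudes": tuple(amps),
        "difference": diff,
        "saturated": bool(diff < tolerance),
    }
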