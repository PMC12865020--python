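"""Epoch cleaning for sham-controlled TMS-EEG.

Fixed order of operations (matching the narrative order of the protocol):
epoch -> baseline correction -> weighted exponential decay fit/subtraction
-> pulse-window cubic interpolation -> downsampling -> trial/channel
rejection. ``preprocess`` runs the full chain.

Time conventions: times in ms relative to the pulse at t = 0; every window
is closed at the lower edge and open at the upper edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .simulate import EpochSet

__all__ = [
    "PreprocParams",
    "DecayFit",
    "RejectionLog",
    "baseline_correct",
    "fit_weights",
    "fit_decay",
    "subtract_decay",
    "interpolate_pulse_window",
    "downsample",
    "reject_bad",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocParams:
    """Cleaning parameters.

    The decay model a*exp(b*t) is fit per trial and channel over
    ``fit_window_ms`` with weights on the squared residuals linearly spaced
    from ``weight_start`` to ``weight_end`` across the window, emphasizing
    the early samples where the artifact dominates. The fit's independent
    variable is in seconds, so b is reported in 1/s.
    """

    epoch_window_ms: tuple[float, float] = (-1500.0, 1500.0)
    baseline_window_ms: tuple[float, float] = (-500.0, -25.0)
    fit_window_ms: tuple[float, float] = (15.0, 500.0)
    weight_start: float = 100.0
    weight_end: float = 1.0
    interp_window_ms: tuple[float, float] = (-5.0, 20.0)
    interp_flank_samples: int = 10
    target_srate: float = 1000.0
    reject_zscore: float = 5.0

    def __post_init__(self) -> None:
        if self.baseline_window_ms[1] > 0:
            raise ValueError("baseline window must precede the pulse")
        if self.fit_window_ms[0] < self.interp_window_ms[0]:
            raise ValueError("fit window must start after the interp window start")
        if not self.weight_start > self.weight_end > 0:
            raise ValueError("need weight_start > weight_end > 0")


@dataclass
class DecayFit:
    """Result of one weighted a*exp(b*t) fit (t in seconds, b in 1/s)."""

    a: float
    b: float
    rss: float  # weighted residual sum of squares
    converged: bool

    def __post_init__(self) -> None:
        if self.converged and not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError("converged fit must have finite parameters")


@dataclass
class RejectionLog:
    """Record of excluded channels and trials with reasons."""

    excluded_channels: list[str] = field(default_factory=list)
    excluded_trials: list[tuple[int, str]] = field(default_factory=list)  # (index, reason)

    def fraction(self, reason: str, n_total: int) -> float:
        if n_total == 0:
            return 0.0
        return sum(1 for _, r in self.excluded_trials if r == reason) / n_total


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    return (times >= window[0]) & (times < window[1])


def baseline_correct(epochs: EpochSet, params: PreprocParams | None = None) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    params = params or PreprocParams()
    m = _window_mask(epochs.times, params.baseline_window_ms)
    if not m.any():
        raise ValueError(
            f"baseline window {params.baseline_window_ms} ms outside the data grid"
        )
    out = epochs.copy()
    out.data = out.data - out.data[:, :, m].mean(axis=2, keepdims=True)
    return out


def fit_weights(n_samples: int, params: PreprocParams | None = None) -> np.ndarray:
    """Linearly spaced fit weights, weight_start at the first fit sample
    down to weight_end at the last."""
    params = params or PreprocParams()
    return np.linspace(params.weight_start, params.weight_end, n_samples)


def fit_decay(
    y: np.ndarray, t_s: np.ndarray, params: PreprocParams | None = None
) -> DecayFit:
    """Weighted least-squares fit of a*exp(b*t) to one time-series.

    ``y`` are the samples over the fit window, ``t_s`` the matching times
    in seconds. The weights multiply the squared residuals. The amplitude
    is profiled out in closed form (for fixed b the optimal a is a weighted
    projection), leaving a bounded 1-D minimization over b — a
    deterministic variable-projection scheme.

    The rate is constrained to b in [-200, 0) 1/s (time constant >= 5 ms):
    faster decays are indistinguishable from the residual pulse artifact
    that the interpolation step removes, and allowing them lets the fit
    chase single samples at the window edge, with explosive backward
    extrapolation toward t = 0.
    """
    params = params or PreprocParams()
    y = np.asarray(y, dtype=float)
    t_s = np.asarray(t_s, dtype=float)
    if y.size == 0:
        raise ValueError("empty fit window")
    if not np.all(np.isfinite(y)):
        raise ValueError("fit input contains non-finite samples")
    w = fit_weights(y.size, params)

    def profiled_rss(b: float) -> tuple[float, float]:
        e = np.exp(b * t_s)
        denom = np.sum(w * e * e)
        a = np.sum(w * e * y) / denom if denom > 0 else 0.0
        r = y - a * e
        return float(np.sum(w * r * r)), float(a)

    try:
        res = optimize.minimize_scalar(
            lambda b: profiled_rss(b)[0],
            bounds=(-200.0, -1e-9),
            method="bounded",
            options={"xatol": 1e-6},
        )
        b = float(res.x)
        rss, a = profiled_rss(b)
        ok = bool(res.success) and np.isfinite(a) and np.isfinite(rss)
    except (ValueError, FloatingPointError):
        return DecayFit(a=np.nan, b=np.nan, rss=np.inf, converged=False)
    if not ok:
        return DecayFit(a=np.nan, b=np.nan, rss=np.inf, converged=False)
    return DecayFit(a=a, b=b, rss=rss, converged=True)


def subtract_decay(
    epochs: EpochSet, params: PreprocParams | None = None
) -> tuple[EpochSet, dict[tuple[int, int], DecayFit]]:
    """Fit and subtract the decay artifact per trial and channel.

    The model is fit over the fit window and the fitted curve is subtracted
    from all post-pulse samples (t >= 0); pre-pulse samples are untouched.
    Non-converged fits are logged and skipped, never abort the batch.
    """
    params = params or PreprocParams()
    fit_mask = _window_mask(epochs.times, params.fit_window_ms)
    if not fit_mask.any():
        raise ValueError("fit window outside the data grid")
    t_fit = epochs.times[fit_mask] / 1000.0
    post = epochs.times >= 0.0
    t_post = epochs.times[post] / 1000.0
    out = epochs.copy()
    fits: dict[tuple[int, int], DecayFit] = {}
    for ti in range(epochs.n_trials):
        for ci in range(len(epochs.channel_names)):
            fit = fit_decay(epochs.data[ti, ci, fit_mask], t_fit, params)
            fits[(ti, ci)] = fit
            if fit.converged:
                out.data[ti, ci, post] -= fit.a * np.exp(fit.b * t_post)
    return out, fits


def interpolate_pulse_window(
    epochs: EpochSet, params: PreprocParams | None = None
) -> EpochSet:
    """Replace samples strictly inside the pulse-artifact window by a cubic.

    A degree-3 polynomial is least-squares fit to ``interp_flank_samples``
    samples on each side of the excised window and evaluated across it, so
    any input that is itself a cubic (or lower-order) polynomial of time is
    reproduced exactly.
    """
    params = params or PreprocParams()
    lo, hi = params.interp_window_ms
    inside = (epochs.times > lo) & (epochs.times < hi)
    if not inside.any():
        return epochs.copy()
    idx = np.where(inside)[0]
    nfl = params.interp_flank_samples
    left = np.arange(max(0, idx[0] - nfl), idx[0])
    right = np.arange(idx[-1] + 1, min(epochs.times.size, idx[-1] + 1 + nfl))
    if left.size < 4 or right.size < 4:
        raise ValueError("interpolation window too close to the epoch edges")
    support = np.concatenate([left, right])
    # center/scale time for conditioning
    t0 = epochs.times[support].mean()
    ts = epochs.times[support] - t0
    scale = np.abs(ts).max()
    vand = np.vander(ts / scale, 4)
    vand_in = np.vander((epochs.times[idx] - t0) / scale, 4)
    out = epochs.copy()
    flat = out.data[:, :, support].reshape(-1, support.size).T
    coef, *_ = np.linalg.lstsq(vand, flat, rcond=None)
    interp = (vand_in @ coef).T.reshape(epochs.n_trials, -1, idx.size)
    out.data[:, :, idx] = interp
    return out


def downsample(epochs: EpochSet, params: PreprocParams | None = None) -> EpochSet:
    """Anti-alias filter and decimate to ``target_srate``.

    The decimation factor must be an integer. A zero-phase 8th-order
    Butterworth low-pass at 0.4x the target Nyquist precedes decimation;
    kept samples are every factor-th sample starting at the first, so the
    output length is ceil(n / factor).
    """
    params = params or PreprocParams()
    ratio = epochs.srate / params.target_srate
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(
            f"decimation factor {ratio} is not an integer "
            f"({epochs.srate} Hz -> {params.target_srate} Hz)"
        )
    out = epochs.copy()
    if q == 1:
        return out
    cutoff = 0.4 * (params.target_srate / 2.0)
    sos = signal.butter(8, cutoff, fs=epochs.srate, output="sos")
    filtered = signal.sosfiltfilt(sos, out.data, axis=-1)
    out.data = np.ascontiguousarray(filtered[:, :, ::q])
    out.times = epochs.times[::q].copy()
    out.srate = params.target_srate
    return out


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.zeros_like(x)
    return (x - med) / (1.4826 * mad)


def reject_bad(
    epochs: EpochSet, params: PreprocParams | None = None
) -> tuple[EpochSet, RejectionLog]:
    """Automated surrogate for visual trial/channel rejection.

    Channels whose median-across-trials peak-to-peak amplitude has a robust
    z-score above ``reject_zscore`` are dropped first; then trials whose
    maximum peak-to-peak over the remaining channels exceeds the same
    robust threshold; finally all MEP-flagged trials. Deterministic given
    input and parameters.
    """
    params = params or PreprocParams()
    log = RejectionLog()
    p2p = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # trials x channels

    ch_metric = np.median(p2p, axis=0)
    ch_z = _robust_z(ch_metric)
    bad_ch = np.where(ch_z > params.reject_zscore)[0]
    keep_ch = np.setdiff1d(np.arange(len(epochs.channel_names)), bad_ch)
    log.excluded_channels = [epochs.channel_names[i] for i in bad_ch]

    tr_metric = p2p[:, keep_ch].max(axis=1) if keep_ch.size else np.zeros(epochs.n_trials)
    tr_z = _robust_z(tr_metric)
    noisy = set(np.where(tr_z > params.reject_zscore)[0].tolist())
    mep = set(np.where(epochs.trial_table["mep_flag"].to_numpy(dtype=bool))[0].tolist())
    for i in sorted(noisy - mep):
        log.excluded_trials.append((i, "noise"))
    for i in sorted(mep):
        log.excluded_trials.append((i, "MEP"))

    keep_tr = np.setdiff1d(np.arange(epochs.n_trials), sorted(noisy | mep))
    if keep_tr.size == 0 and epochs.n_trials > 0:
        raise ValueError(
            f"all trials rejected at robust z threshold {params.reject_zscore}"
        )
    out = EpochSet(
        data=epochs.data[np.ix_(keep_tr, keep_ch)],
        times=epochs.times.copy(),
        channel_names=[epochs.channel_names[i] for i in keep_ch],
        srate=epochs.srate,
        trial_table=epochs.trial_table.iloc[keep_tr].reset_index(drop=True),
    )
    return out, log


def preprocess(
    epochs: EpochSet, params: PreprocParams | None = None, skip_decay: bool = False
) -> tuple[EpochSet, RejectionLog]:
    """Full cleaning chain in the documented order.

    A hook point for subspace artifact suppression and ocular-component
    removal (third-party algorithms) would sit between interpolation and
    downsampling; the synthetic generator does not require them.
    """
    params = params or PreprocParams()
    out = baseline_correct(epochs, params)
    if not skip_decay:
        out, _ = subtract_decay(out, params)
    out = interpolate_pulse_window(out, params)
    out = downsample(out, params)
    return reject_bad(out, params)
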