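"""Synthetic TMS-EEG session generator.

Emulates the statistical structure of a sham-controlled TMS-EEG experiment:
8 blocks (2 cortical targets x 4 sham conditions), each with randomly
interleaved real-TMS and sham-TMS trials, 64-channel epochs sampled at
5 kHz from -1500 to +1500 ms around the pulse.

Evoked content
    * target-specific TEP components (Gaussian bumps with 2D Gaussian
      sensor topographies), present only in real-TMS trials;
    * a frontocentral N100/P200/N300 PEP complex in every trial, whose
      amplitude follows a saturating (Hill) function of the somatosensory
      stimulus intensity plus a fixed auditory share.

Nuisance content
    * a per-channel exponential decay artifact a*exp(b*t) after the pulse
      (all trials: the artifact originates from the scalp electric
      stimulation and the pulse, both present in real and sham trials);
    * a high-amplitude pulse artifact confined to the -5..20 ms window;
    * 1/f + white noise;
    * MEP-contaminated real-TMS trials flagged at a configurable rate.

All randomness flows from a single master seed through per-subject
``numpy.random.SeedSequence`` streams, so identical designs and seeds give
bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .layout import CHANNELS_64, gaussian_topography, sensor_positions_2d

__all__ = [
    "ShamCondition",
    "SessionDesign",
    "ComponentTemplate",
    "PEPResponseCurve",
    "DecayParams",
    "EpochSet",
    "ParcelSet",
    "pep_amplitude",
    "simulate_onsets",
    "build_trial_table",
    "evaluate_templates",
    "simulate_session",
    "simulate_parcels",
    "default_tep_components",
    "default_pep_components",
    "default_conditions",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ShamCondition:
    """One sham-procedure cell of the factorial design.

    ``es_site`` is where the transcutaneous electric stimulation (ES) is
    applied; ``es_mode`` is 'calibrated' (intensity titrated so the sham PEP
    matches the real-TMS PEP) or 'fixed' (a fixed multiple of the
    somatosensory perception threshold, the PEP-saturation design);
    ``es_in_real`` says whether the ES is also delivered during real TMS.
    """

    name: str
    es_site: str  # 'scalp' | 'shoulder'
    es_mode: str  # 'calibrated' | 'fixed'
    es_intensity: float  # % of perception threshold, applied in sham trials
    es_in_real: bool


def default_conditions() -> list[ShamCondition]:
    """The four sham conditions of the reference design.

    Conditions 2 and 3 are the PEP-saturation design (scalp ES at 300% and
    600% of the perception threshold, delivered in both real and sham
    trials). Conditions 1 and 4 are the calibrated design (scalp and
    shoulder ES respectively, sham trials only); their default intensities
    are free parameters of the generator, set to the generator's effective
    real-TMS somatosensory intensity so that PEPs match by construction.
    """
    return [
        ShamCondition("cond1", "scalp", "calibrated", 150.0, False),
        ShamCondition("cond2", "scalp", "fixed", 300.0, True),
        ShamCondition("cond3", "scalp", "fixed", 600.0, True),
        ShamCondition("cond4", "shoulder", "calibrated", 150.0, False),
    ]


@dataclass(frozen=True)
class SessionDesign:
    """Factorial description of a TMS-EEG session.

    Defaults reproduce the reference design: 2 targets x 4 sham conditions
    = 8 blocks, 140 real + 140 sham trials per block (280 per block, 2240
    per experiment), mean ISI 2.5 s with +/-0.5 s uniform jitter, 64
    channels at 5 kHz, epochs -1500..1500 ms, ~5.8% of real-TMS trials
    contaminated by MEPs.
    """

    targets: tuple[str, ...] = ("M1", "SMA")
    conditions: tuple[ShamCondition, ...] = field(
        default_factory=lambda: tuple(default_conditions())
    )
    trials_per_cell: int = 140
    isi_mean: float = 2.5
    isi_jitter: float = 0.5
    sampling_rate: float = 5000.0
    n_channels: int = 64
    n_subjects: int = 20
    mep_rate: float = 0.058
    epoch_window_ms: tuple[float, float] = (-1500.0, 1500.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_cell < 0:
            raise ValueError("trials_per_cell must be >= 0")
        if self.isi_jitter > self.isi_mean:
            raise ValueError("isi_jitter must not exceed isi_mean")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0.0 <= self.mep_rate <= 1.0:
            raise ValueError("mep_rate must be in [0, 1]")
        if self.epoch_window_ms[0] >= self.epoch_window_ms[1]:
            raise ValueError("epoch window must be increasing")

    @property
    def n_blocks(self) -> int:
        return len(self.targets) * len(self.conditions)

    @property
    def trials_per_block(self) -> int:
        return 2 * self.trials_per_cell

    @property
    def trials_per_experiment(self) -> int:
        return self.n_blocks * self.trials_per_block

    def times_ms(self) -> np.ndarray:
        """Sample grid in ms, half-open [start, end), pulse at t=0."""
        step = 1000.0 / self.sampling_rate
        n = int(round((self.epoch_window_ms[1] - self.epoch_window_ms[0]) / step))
        return self.epoch_window_ms[0] + step * np.arange(n)


@dataclass(frozen=True)
class ComponentTemplate:
    """A single evoked component: Gaussian bump in time, fixed topography.

    ``latency_ms`` is the bump center, ``width_ms`` its temporal SD,
    ``amplitude_uv`` the signed peak value at the topography's unit-weight
    channel.
    """

    label: str
    latency_ms: float
    width_ms: float
    amplitude_uv: float
    topography: np.ndarray  # per-channel weights, unit max-abs

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        topo = np.asarray(self.topography, dtype=float)
        if not np.any(topo != 0):
            raise ValueError("topography must have a nonzero entry")
        object.__setattr__(self, "topography", topo)

    def waveform(self, times_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(times_ms, dtype=float)
        return self.amplitude_uv * np.exp(
            -((t - self.latency_ms) ** 2) / (2.0 * self.width_ms**2)
        )


@dataclass(frozen=True)
class PEPResponseCurve:
    """Saturating PEP amplitude vs somatosensory stimulus intensity.

    Hill form ``baseline + (a_max - baseline) * I^h / (I^h + i_half^h)``.
    Defaults place >95% saturation at 300% of the perception threshold,
    with a 300%-vs-600% amplitude gap below 0.5 µV.
    """

    a_max: float = 20.0  # µV, asymptotic PEP peak-to-peak amplitude
    i_half: float = 100.0  # % of perception threshold at half saturation
    h: float = 4.0  # Hill exponent
    baseline: float = 0.0  # µV at zero intensity

    def __post_init__(self) -> None:
        if self.a_max <= 0 or self.i_half <= 0 or self.h <= 0:
            raise ValueError("a_max, i_half and h must be positive")


def pep_amplitude(intensity: float | np.ndarray, curve: PEPResponseCurve) -> float | np.ndarray:
    """PEP scaling (µV) at an ES intensity in % of perception threshold.

    Monotone nondecreasing; tends to ``curve.a_max`` as intensity grows.
    """
    i = np.asarray(intensity, dtype=float)
    if np.any(i < 0):
        raise ValueError("intensity must be >= 0")
    ih = i**curve.h
    out = curve.baseline + (curve.a_max - curve.baseline) * ih / (ih + curve.i_half**curve.h)
    return float(out) if np.isscalar(intensity) else out


@dataclass(frozen=True)
class DecayParams:
    """Exponential decay artifact a*exp(b*t), t in seconds after the pulse.

    The default rate (time constant 20 ms) confines the artifact to the
    first tens of milliseconds, where it is observed.
    """

    a: float = 40.0  # µV at t=0 on the most affected channel
    b: float = -50.0  # 1/s, must be negative
    channel_scale: np.ndarray | None = None  # per-channel multiplier

    def __post_init__(self) -> None:
        if self.b >= 0:
            raise ValueError("decay rate b must be negative")


@dataclass
class EpochSet:
    """Trials x channels x samples EEG container with per-trial metadata."""

    data: np.ndarray  # (n_trials, n_channels, n_samples), µV
    times: np.ndarray  # ms relative to the pulse, strictly increasing
    channel_names: list[str]
    srate: float
    trial_table: pd.DataFrame  # subject, target, condition, stim_type, ...

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel dimension mismatch")
        if self.data.shape[2] != self.times.size:
            raise ValueError("sample dimension mismatch")
        if self.data.shape[0] != len(self.trial_table):
            raise ValueError("trial dimension mismatch")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if len(self.trial_table) and self.trial_table["stim_type"].isna().any():
            raise ValueError("every trial needs a stim_type")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            times=self.times.copy(),
            channel_names=list(self.channel_names),
            srate=self.srate,
            trial_table=self.trial_table.loc[mask].reset_index(drop=True),
        )

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            times=self.times.copy(),
            channel_names=list(self.channel_names),
            srate=self.srate,
            trial_table=self.trial_table.copy(),
        )


@dataclass
class ParcelSet:
    """Parcel-space stand-in for source-reconstructed time-courses."""

    data: np.ndarray  # (n_trials, n_parcels, n_samples), standardized units
    times: np.ndarray
    labels: list[str]
    positions: np.ndarray  # (n_parcels, 2)
    adjacency: list[set[int]]  # symmetric, no self-edges
    srate: float
    trial_table: pd.DataFrame

    def __post_init__(self) -> None:
        for i, nbrs in enumerate(self.adjacency):
            if i in nbrs:
                raise ValueError("adjacency must have no self-edges")
            for j in nbrs:
                if i not in self.adjacency[j]:
                    raise ValueError("adjacency must be symmetric")


# --------------------------------------------------------------------------
# defaults: components and conditions
# --------------------------------------------------------------------------

def default_tep_components(
    channels: list[str] | None = None,
    targets: tuple[str, ...] = ("M1", "SMA"),
) -> dict[str, list[ComponentTemplate]]:
    """Target-specific TEP component sets.

    M1: P30/N45 over the stimulated sensorimotor cortex, P60 over premotor
    areas, P120 over sensorimotor cortex. SMA: P25 over ipsilateral
    sensorimotor cortex, N40 lateral-posterior, P55 over the midline SMA.
    Amplitudes are in the low-µV range typical of sham-subtracted TEPs.
    """
    channels = list(channels) if channels is not None else list(CHANNELS_64)
    pos = sensor_positions_2d(channels)

    def topo(center: str, spread: float = 0.35) -> np.ndarray:
        return gaussian_topography(center, spread, channels, pos)

    builders = {
        "M1": lambda: [
            ComponentTemplate("P30", 30.0, 5.0, 2.5, topo("C3")),
            ComponentTemplate("N45", 45.0, 7.0, -3.0, topo("C3")),
            ComponentTemplate("P60", 60.0, 9.0, 2.0, topo("FC3")),
            ComponentTemplate("P120", 120.0, 18.0, 2.0, topo("C3")),
        ],
        "SMA": lambda: [
            ComponentTemplate("P25", 25.0, 5.0, 2.0, topo("C3")),
            ComponentTemplate("N40", 40.0, 7.0, -2.0, topo("P5")),
            ComponentTemplate("P55", 55.0, 9.0, 3.0, topo("FCz")),
        ],
    }
    unknown = [t for t in targets if t not in builders]
    if unknown:
        raise KeyError(f"no default components for targets {unknown}")
    return {t: builders[t]() for t in targets}


def default_pep_components(
    channels: list[str] | None = None,
) -> list[ComponentTemplate]:
    """Frontocentral PEP complex (N100, P200, N300) at unit scale.

    Relative amplitudes are normalized so that at scale 1 the FCz
    peak-to-peak amplitude — max over [170, 230) ms minus min over
    [280, 350) ms, the calibration estimator's definition — equals exactly
    1. Multiplying by ``pep_amplitude(I, curve)`` therefore yields that
    peak-to-peak value in µV.
    """
    channels = list(channels) if channels is not None else list(CHANNELS_64)
    pos = sensor_positions_2d(channels)
    topo = gaussian_topography("FCz", 0.45, channels, pos)
    raw = [
        ComponentTemplate("N100", 100.0, 18.0, -0.9, topo),
        ComponentTemplate("P200", 200.0, 35.0, 0.65, topo),
        ComponentTemplate("N300", 310.0, 40.0, -0.5, topo),
    ]
    # normalize on a dense grid at the unit-weight channel
    t = np.arange(150.0, 360.0, 0.1)
    wave = sum(c.waveform(t) for c in raw)
    p2p = wave[(t >= 170) & (t < 230)].max() - wave[(t >= 280) & (t < 350)].min()
    return [replace(c, amplitude_uv=c.amplitude_uv / p2p) for c in raw]


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def simulate_onsets(
    n_events: int,
    isi_mean: float,
    isi_jitter: float,
    rng: np.random.Generator,
    start: float = 0.0,
) -> np.ndarray:
    """Event onset times (s): successive gaps isi_mean + U(-jitter, +jitter)."""
    if n_events <= 0:
        return np.empty(0)
    isis = isi_mean + rng.uniform(-isi_jitter, isi_jitter, size=n_events - 1)
    return start + np.concatenate([[0.0], np.cumsum(isis)])


def build_trial_table(
    design: SessionDesign, subject: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Chronological trial table for one subject's session.

    Blocks (target x condition cells, order randomized) each hold
    ``trials_per_cell`` real and ``trials_per_cell`` sham trials in a
    random interleaving; onsets follow the jittered-ISI model with blocks
    laid out back-to-back (1 min between blocks). MEP flags are drawn
    per real-TMS trial with probability ``mep_rate``.
    """
    cells = [(t, c) for t in design.targets for c in design.conditions]
    order = rng.permutation(len(cells))
    rows: list[dict] = []
    t0 = 0.0
    for bi, ci in enumerate(order):
        target, cond = cells[ci]
        n = design.trials_per_cell
        stim = np.array(["real"] * n + ["sham"] * n)
        rng.shuffle(stim)
        onsets = simulate_onsets(2 * n, design.isi_mean, design.isi_jitter, rng, start=t0)
        if len(onsets):
            t0 = onsets[-1] + 60.0  # inter-block break
        for k in range(2 * n):
            real = stim[k] == "real"
            rows.append(
                {
                    "subject": subject,
                    "block": bi,
                    "target": target,
                    "condition": cond.name,
                    "stim_type": stim[k],
                    "onset_s": onsets[k] if len(onsets) else np.nan,
                    "mep_flag": bool(real and rng.random() < design.mep_rate),
                    "es_intensity": cond.es_intensity
                    if (not real or cond.es_in_real)
                    else 0.0,
                }
            )
    cols = [
        "subject", "block", "target", "condition", "stim_type",
        "onset_s", "mep_flag", "es_intensity",
    ]
    return pd.DataFrame(rows, columns=cols)


def evaluate_templates(
    components: list[ComponentTemplate], times_ms: np.ndarray
) -> np.ndarray:
    """Pointwise sum of component templates -> (n_channels, n_samples)."""
    if not components:
        raise ValueError("need at least one component")
    n_ch = components[0].topography.size
    out = np.zeros((n_ch, np.asarray(times_ms).size))
    for c in components:
        out += np.outer(c.topography, c.waveform(times_ms))
    return out


def _pink_noise(rng: np.random.Generator, n_ch: int, n_samp: int) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise, independent per channel."""
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samp)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n=n_samp, axis=-1)
    rms = pink.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return pink / rms


def _pulse_artifact(times_ms: np.ndarray, amp: float) -> np.ndarray:
    """Damped 300 Hz oscillation confined to the -5..20 ms window."""
    wave = np.zeros_like(times_ms)
    if amp == 0:
        return wave
    m = (times_ms >= -5.0) & (times_ms < 20.0)
    t = times_ms[m]
    env = np.exp(-np.clip(t, 0, None) / 5.0) * np.clip((t + 5.0) / 5.0, 0.0, 1.0)
    wave[m] = amp * env * np.cos(2 * np.pi * 0.3 * t)
    return wave


def simulate_session(
    design: SessionDesign,
    components: dict[str, list[ComponentTemplate]] | None = None,
    pep_curve: PEPResponseCurve | None = None,
    decay: DecayParams | None = None,
    noise_level: float = 3.0,
    seed: int | None = None,
    channels: list[str] | None = None,
    pep_components: list[ComponentTemplate] | None = None,
    auditory_pep_uv: float = 3.0,
    real_es_equivalent: float = 150.0,
    pep_mismatch: float = 0.0,
    pulse_artifact_uv: float = 500.0,
    subject_amp_sd: float = 0.2,
    pink_fraction: float = 0.6,
    mep_bump_uv: float = 0.0,
) -> list[EpochSet]:
    """Simulate one EpochSet per subject under the given design.

    Real-TMS trials = TEP templates + scaled PEP complex + decay artifact +
    pulse artifact + noise; sham trials = scaled PEP complex (including the
    identical auditory share) + decay artifact + pulse artifact + noise,
    no TEP. The decay and pulse artifacts are shared between real and sham
    trials, as both stem from the electric stimulation and coil discharge
    common to the two.

    ``real_es_equivalent`` is the effective somatosensory intensity (% of
    perception threshold) attributed to the real TMS pulse itself when no
    ES is co-delivered; ``pep_mismatch`` multiplies the sham PEP by
    (1 + mismatch) to emulate a calibration failure; ``subject_amp_sd`` is
    the SD of a per-subject multiplicative gain on all evoked content.
    """
    if design.sampling_rate <= 0:
        raise ValueError("sampling rate must be positive")
    channels = list(channels) if channels is not None else list(CHANNELS_64[: design.n_channels])
    if len(channels) != design.n_channels:
        raise ValueError("channel list length must match design.n_channels")
    components = (
        components
        if components is not None
        else default_tep_components(channels, tuple(design.targets))
    )
    pep_curve = pep_curve if pep_curve is not None else PEPResponseCurve()
    decay = decay if decay is not None else DecayParams()
    pep_components = (
        pep_components if pep_components is not None else default_pep_components(channels)
    )
    times = design.times_ms()
    lo, hi = design.epoch_window_ms
    for target in design.targets:
        if target not in components:
            raise KeyError(f"no components for target {target!r}")
        for c in components[target]:
            if not (lo <= c.latency_ms < hi):
                raise ValueError(
                    f"component {c.label!r} latency {c.latency_ms} ms outside "
                    f"epoch window [{lo}, {hi}) ms"
                )

    tep_templates = {t: evaluate_templates(components[t], times) for t in design.targets}
    pep_unit = evaluate_templates(pep_components, times)
    ch_scale = (
        np.ones(len(channels)) if decay.channel_scale is None
        else np.asarray(decay.channel_scale, dtype=float)
    )
    t_s = np.clip(times, 0.0, None) / 1000.0
    decay_template = (
        decay.a * np.outer(ch_scale, np.exp(decay.b * t_s)) * (times >= 0.0)
    )
    pulse = _pulse_artifact(times, pulse_artifact_uv)
    cond_by_name = {c.name: c for c in design.conditions}
    mep_topo = gaussian_topography("C3", 0.35, channels) if mep_bump_uv else None

    master = np.random.SeedSequence(design.seed if seed is None else seed)
    out: list[EpochSet] = []
    for subj, child in enumerate(master.spawn(design.n_subjects)):
        rng = np.random.default_rng(child)
        table = build_trial_table(design, subj, rng)
        gain = 1.0 + subject_amp_sd * rng.standard_normal() if subject_amp_sd else 1.0
        data = np.zeros((len(table), len(channels), times.size))
        for k in range(len(table)):
            row = table.iloc[k]
            real = row["stim_type"] == "real"
            cond = cond_by_name[row["condition"]]
            if real:
                es_eff = cond.es_intensity if cond.es_in_real else real_es_equivalent
            else:
                es_eff = cond.es_intensity
            pep_scale = pep_amplitude(es_eff, pep_curve) + auditory_pep_uv
            if not real:
                pep_scale *= 1.0 + pep_mismatch
            trial = gain * pep_scale * pep_unit + decay_template + pulse[None, :]
            if real:
                trial = trial + gain * tep_templates[row["target"]]
                if row["mep_flag"] and mep_bump_uv:
                    bump = mep_bump_uv * np.exp(-((times - 45.0) ** 2) / (2 * 8.0**2))
                    trial = trial + np.outer(mep_topo, bump)
            if noise_level:
                pink = _pink_noise(rng, len(channels), times.size)
                white = rng.standard_normal((len(channels), times.size))
                trial = trial + noise_level * (
                    np.sqrt(pink_fraction) * pink + np.sqrt(1 - pink_fraction) * white
                )
            data[k] = trial
        out.append(
            EpochSet(
                data=data,
                times=times.copy(),
                channel_names=list(channels),
                srate=design.sampling_rate,
                trial_table=table,
            )
        )
    return out


def simulate_amplitude_table(
    n_subjects: int = 20,
    n_conditions: int = 4,
    true_d: float = 0.0,
    shifted_condition: int = 1,
    between_sd: float = 4.0,
    within_sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Subjects x conditions windowed-amplitude table for group statistics.

    Repeated-measures structure: amplitude = subject effect (SD
    ``between_sd``) + condition noise (SD ``within_sd``); between-subject
    variability dominates, as it does for trial-averaged evoked
    amplitudes. ``true_d`` shifts ``shifted_condition`` by
    d x pooled SD (Cohen's d on the across-subject scale).
    """
    rng = rng if rng is not None else np.random.default_rng()
    subj = between_sd * rng.standard_normal(n_subjects)
    table = subj[:, None] + within_sd * rng.standard_normal((n_subjects, n_conditions))
    if true_d:
        pooled = np.sqrt(between_sd**2 + within_sd**2)
        table[:, shifted_condition] += true_d * pooled
    return table


def simulate_parcels(
    epochs: EpochSet,
    n_parcels: int = 290,
    seed: int | None = None,
    k_neighbors: int = 4,
    parcel_noise: float = 0.05,
    spread: float = 0.15,
) -> ParcelSet:
    """Project sensor epochs onto a synthetic parcel space.

    A stand-in for source reconstruction: parcels get fixed pseudo-random
    positions on the unit disk, sensor signals are mixed through a local
    Gaussian sensor->parcel projection, and adjacency is a symmetrized
    k-nearest-neighbor graph over parcel positions (planar-like).
    """
    if n_parcels < 4:
        raise ValueError("n_parcels must be >= 4 (minimum-neighbor rule unusable)")
    rng = np.random.default_rng(seed)
    # parcel positions: sunflower spiral (deterministic given count) + jitter
    k = np.arange(n_parcels) + 0.5
    r = np.sqrt(k / n_parcels)
    phi = np.pi * (1 + np.sqrt(5)) * k
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    pos = pos + 0.01 * rng.standard_normal(pos.shape)

    sens = sensor_positions_2d(epochs.channel_names)
    sens = sens / np.abs(sens).max()  # into the unit disk
    d2 = ((pos[:, None, :] - sens[None, :, :]) ** 2).sum(-1)
    weights = np.exp(-d2 / (2.0 * spread**2))
    weights = weights / weights.sum(axis=1, keepdims=True)

    data = np.einsum("pc,tcs->tps", weights, epochs.data)
    if parcel_noise:
        data = data + parcel_noise * rng.standard_normal(data.shape)

    dmat = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(dmat, np.inf)
    adjacency: list[set[int]] = [set() for _ in range(n_parcels)]
    for i in range(n_parcels):
        for j in np.argsort(dmat[i])[:k_neighbors]:
            adjacency[i].add(int(j))
            adjacency[int(j)].add(i)

    return ParcelSet(
        data=data,
        times=epochs.times.copy(),
        labels=[f"parcel{i:03d}" for i in range(n_parcels)],
        positions=pos,
        adjacency=adjacency,
        srate=epochs.srate,
        trial_table=epochs.trial_table.copy(),
    )
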