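"""Condition averaging and sham-subtraction TEP isolation.

The sham-controlled logic: components present in both real- and sham-TMS
responses are peripherally evoked (PEPs); subtracting the condition's sham
evoked response from its real evoked response leaves the TMS-evoked
potential (TEP), assuming linear superposition of the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import EpochSet, ParcelSet

__all__ = [
    "EvokedResponse",
    "TepEstimate",
    "average_condition",
    "subtract_sham",
    "standardize_trials",
]


@dataclass
class EvokedResponse:
    """Trial-averaged response for one (target, condition, stim_type) cell."""

    data: np.ndarray  # channels x samples
    times: np.ndarray  # ms
    channel_names: list[str]
    n_trials: int
    target: str
    condition: str
    stim_type: str

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if self.data.shape != (len(self.channel_names), self.times.size):
            raise ValueError("data shape inconsistent with channels/times")


@dataclass
class TepEstimate:
    """Real-minus-sham difference wave, with provenance."""

    data: np.ndarray  # channels x samples
    times: np.ndarray
    channel_names: list[str]
    target: str
    condition: str
    n_trials_real: int
    n_trials_sham: int


def average_condition(
    epochs: EpochSet,
    target: str | None = None,
    condition: str | None = None,
    stim_type: str | None = None,
) -> EvokedResponse:
    """Arithmetic mean over the trials matching the selector."""
    tab = epochs.trial_table
    mask = np.ones(len(tab), dtype=bool)
    if target is not None:
        mask &= (tab["target"] == target).to_numpy()
    if condition is not None:
        mask &= (tab["condition"] == condition).to_numpy()
    if stim_type is not None:
        mask &= (tab["stim_type"] == stim_type).to_numpy()
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            f"no trials match target={target!r} condition={condition!r} "
            f"stim_type={stim_type!r}"
        )
    return EvokedResponse(
        data=epochs.data[mask].mean(axis=0),
        times=epochs.times.copy(),
        channel_names=list(epochs.channel_names),
        n_trials=n,
        target=target or "any",
        condition=condition or "any",
        stim_type=stim_type or "any",
    )


def subtract_sham(real: EvokedResponse, sham: EvokedResponse) -> TepEstimate:
    """Pointwise real-minus-sham difference; grids and cell must match."""
    if real.channel_names != sham.channel_names:
        raise ValueError("channel sets differ between real and sham responses")
    if real.times.shape != sham.times.shape or not np.allclose(real.times, sham.times):
        raise ValueError("time grids differ between real and sham responses")
    if (real.target, real.condition) != (sham.target, sham.condition):
        raise ValueError("real and sham responses come from different cells")
    return TepEstimate(
        data=real.data - sham.data,
        times=real.times.copy(),
        channel_names=list(real.channel_names),
        target=real.target,
        condition=real.condition,
        n_trials_real=real.n_trials,
        n_trials_sham=sham.n_trials,
    )


def standardize_trials(parcels: ParcelSet) -> tuple[ParcelSet, list[int]]:
    """z-transform each trial's signal to zero mean and unit SD.

    The statistics are taken over the whole trial (all parcels and
    samples), so the per-trial output is invariant to affine transforms of
    the input. Zero-variance trials cannot be standardized; they are
    dropped and their original indices returned.
    """
    flat = parcels.data.reshape(parcels.data.shape[0], -1)
    mean = flat.mean(axis=1)
    sd = flat.std(axis=1)
    bad = np.where(sd == 0)[0]
    keep = np.where(sd > 0)[0]
    data = (parcels.data[keep] - mean[keep, None, None]) / sd[keep, None, None]
    out = ParcelSet(
        data=data,
        times=parcels.times.copy(),
        labels=list(parcels.labels),
        positions=parcels.positions.copy(),
        adjacency=[set(s) for s in parcels.adjacency],
        srate=parcels.srate,
        trial_table=parcels.trial_table.iloc[keep].reset_index(drop=True),
    )
    return out, bad.tolist()
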