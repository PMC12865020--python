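"""Idealized 64-channel EEG sensor layout.

Channel positions come from the bundled standard 10-05 montage and are
flattened to 2D with an azimuthal-equidistant projection (the usual
"topomap" view), which is what the topography builders and the
distance-based neighbor rules operate on.
"""

from __future__ import annotations

import warnings

import numpy as np

#: The 64 channels simulated by the session generator (10-10 subset of an
#: extended cap; includes the frontocentral reference sites used by the
#: PEP estimator and the sensorimotor sites used by the TEP templates).
CHANNELS_64 = [
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
    "FT9", "FT10", "Iz",
]


def _montage_positions() -> dict[str, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            mon = mne.channels.make_standard_montage("colin27_1005")
        except ValueError:  # older naming
            mon = mne.channels.make_standard_montage("standard_1005")
    return mon.get_positions()["ch_pos"]


def sensor_positions_2d(channels: list[str] | None = None) -> np.ndarray:
    """Return (n_channels, 2) projected sensor coordinates.

    Azimuthal-equidistant projection of the montage's 3D positions about
    the vertex: radius = polar angle from +z, angle = azimuth. Units are
    radians of polar angle (vertex Cz maps to ~(0, 0)).
    """
    channels = list(channels) if channels is not None else list(CHANNELS_64)
    pos3 = _montage_positions()
    missing = [ch for ch in channels if ch not in pos3]
    if missing:
        raise KeyError(f"channels not in montage: {missing}")
    xyz = np.array([pos3[ch] for ch in channels], dtype=float)
    # center on the head sphere origin (montage is roughly head-centered)
    xyz = xyz - xyz.mean(axis=0) * np.array([1.0, 1.0, 0.0])
    r = np.linalg.norm(xyz, axis=1)
    theta = np.arccos(np.clip(xyz[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(xyz[:, 1], xyz[:, 0])
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


def gaussian_topography(
    center: str,
    spread: float,
    channels: list[str] | None = None,
    positions: np.ndarray | None = None,
) -> np.ndarray:
    """2D Gaussian channel weighting centered on a named sensor.

    Weights are normalized to unit maximum absolute value, so a component
    amplitude in µV is attained exactly at the center channel.
    """
    channels = list(channels) if channels is not None else list(CHANNELS_64)
    if positions is None:
        positions = sensor_positions_2d(channels)
    if spread <= 0:
        raise ValueError("spread must be positive")
    idx = channels.index(center)
    d2 = np.sum((positions - positions[idx]) ** 2, axis=1)
    w = np.exp(-d2 / (2.0 * spread**2))
    return w / np.abs(w).max()
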