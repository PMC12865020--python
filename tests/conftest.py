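import numpy as np
import pytest

from tepkit.cluster import NeighborGraph
from tepkit.simulate import DecayParams, SessionDesign, simulate_session


@pytest.fixture
def ring_graph() -> NeighborGraph:
    """6-node ring, the small parcel-like graph used in cluster tests."""
    return NeighborGraph(
        labels=[f"n{i}" for i in range(6)],
        adjacency=[{(i - 1) % 6, (i + 1) % 6} for i in range(6)],
    )


#: simulate_session keyword arguments that switch off every nuisance
#: process (noise, decay, pulse artifact, subject gain variability)
CLEAN_KWARGS = dict(
    noise_level=0.0,
    pulse_artifact_uv=0.0,
    subject_amp_sd=0.0,
    decay=DecayParams(a=0.0, b=-15.0),
)


@pytest.fixture
def clean_kwargs() -> dict:
    return dict(CLEAN_KWARGS)


@pytest.fixture
def small_design() -> SessionDesign:
    """One M1 target, 4 conditions, short 1 kHz epochs: fast but covers the
    baseline window and all estimator/equivalence windows."""
    return SessionDesign(
        targets=("M1",),
        trials_per_cell=3,
        n_subjects=1,
        sampling_rate=1000.0,
        epoch_window_ms=(-600.0, 600.0),
        n_channels=32,
        mep_rate=0.0,
        seed=11,
    )


@pytest.fixture
def small_session(small_design, clean_kwargs):
    return simulate_session(small_design, **clean_kwargs)[0]
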