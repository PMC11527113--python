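import numpy as np
import pytest

from supercoilfret import (
    ExcitationSchedule,
    NoiseModel,
    PhotophysicsModel,
    Trace,
)


@pytest.fixture
def clean_photophysics():
    """No bleaching, no inactive acceptors, full labeling."""
    return PhotophysicsModel(
        donor_bleach=0.0,
        acceptor_bleach=0.0,
        inactive_acceptor_fraction=0.0,
        labeled_fraction=1.0,
    )


@pytest.fixture
def noiseless():
    return NoiseModel(total_intensity=1000.0, intensity_sd=0.0, background=0.0)


def make_constant_trace(
    donor: float,
    acceptor: float,
    schedule: ExcitationSchedule | None = None,
    frame_interval: float = 0.05,
    molecule_id: int = 0,
) -> Trace:
    """Trace with constant intensities on every frame."""
    if schedule is None:
        schedule = ExcitationSchedule.cas9_snapshot()
    n = schedule.n_frames
    return Trace(
        molecule_id=molecule_id,
        donor=np.full(n, float(donor)),
        acceptor=np.full(n, float(acceptor)),
        frame_interval=frame_interval,
        schedule=schedule,
    )
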