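import numpy as np
import pytest

from freegaze.geometry import GazeRecording, GeometrySpec
from freegaze.synthetic import generate_images, map_driven_cohort, simulate_session

SR = 500.0
PPD = 40.6


@pytest.fixture(scope="session")
def geom() -> GeometrySpec:
    return GeometrySpec()


@pytest.fixture(scope="session")
def small_geom() -> GeometrySpec:
    """A 100 px (~2.46°) raster for cheap map-space tests."""
    return GeometrySpec(image_size_px=(100, 100),
                        image_extent_deg=(100 / PPD, 100 / PPD))


def build_recording(
    x, y, valid=None, geometry=None, participant_id="p1", group="SC",
    image_id="imgA", trial_index=1, block=1, presentation=1,
) -> GazeRecording:
    x = np.asarray(x, dtype=float)
    geometry = geometry or GeometrySpec()
    if valid is None:
        valid = np.ones(len(x), dtype=bool)
    return GazeRecording(
        participant_id=participant_id, group=group, image_id=image_id,
        trial_index=trial_index, block=block,
        t=np.arange(len(x)) / geometry.sampling_rate,
        x=x, y=np.asarray(y, dtype=float), valid=np.asarray(valid, dtype=bool),
        geometry=geometry,
    )


@pytest.fixture(scope="session")
def truth_maps():
    """Three synthetic ground-truth attention maps (no pixel rendering)."""
    _, maps = generate_images(3, seed=5, render_pixels=False)
    return maps


@pytest.fixture(scope="session")
def small_session():
    """A 4-participant map-driven session with a reduced 7-trial design
    (2 same-image / 2 same-category / 3 different-category pairs)."""
    cohort = map_driven_cohort(n_participants=4, seed=7)
    return simulate_session(cohort, pair_mix=(2, 2, 3))


@pytest.fixture(scope="session")
def nystagmus_session():
    """Same reduced design, explored with horizontal-jerk kinematics."""
    cohort = map_driven_cohort(n_participants=4, seed=9, profile="horizontal_jerk")
    return simulate_session(cohort, pair_mix=(2, 2, 3))
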