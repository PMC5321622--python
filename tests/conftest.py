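import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from casm import (
    FrameCoordinates,
    SwallowSeries,
    default_registry,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def rng():
    return np.random.default_rng(20160825)


def build_series(
    coords: np.ndarray,
    video_id: str = "v001",
    rater_id: str = "R1",
    trial_id: str = "T1",
    frame_rate: float = 30.0,
) -> SwallowSeries:
    """Series from an (n_frames, 12, 2) coordinate array."""
    frames = tuple(
        FrameCoordinates(video_id=video_id, frame_index=i, points=coords[i])
        for i in range(coords.shape[0])
    )
    return SwallowSeries(
        video_id=video_id,
        frames=frames,
        rater_id=rater_id,
        trial_id=trial_id,
        frame_rate=frame_rate,
    )


@pytest.fixture
def random_series(rng):
    """30 frames of jittered template coordinates."""
    from casm.synthetic import DEFAULT_TEMPLATE

    coords = DEFAULT_TEMPLATE[None] + rng.normal(0, 3, size=(30, 12, 2))
    return build_series(coords)


@pytest.fixture
def random_shape(rng):
    return rng.normal(0, 20, size=(12, 2))
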