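import numpy as np
import pytest

from monoloc import CArmPose, pose_to_geometry
from monoloc.phantom import PhantomSpec, default_pose, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def identity_geom():
    return pose_to_geometry(default_pose())


@pytest.fixture
def phantom_scene():
    """Default arch+carotid phantom with on-centerline markers."""
    spec = PhantomSpec(seed=7)
    tree, markers, truth = make_phantom(spec)
    return spec, tree, markers, truth


def random_pose(rng) -> CArmPose:
    sod = rng.uniform(600, 850)
    return CArmPose(
        primary_angle_deg=rng.uniform(-90, 90),
        secondary_angle_deg=rng.uniform(-40, 40),
        sod_mm=sod,
        sid_mm=sod + rng.uniform(150, 400),
        pixel_spacing_mm=(rng.uniform(0.2, 0.4),) * 2,
        detector_size_px=(512, 512),
    )
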