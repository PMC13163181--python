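import numpy as np
import pytest

import polypcam as pc


@pytest.fixture(scope="session")
def fisheye_camera() -> pc.CameraModel:
    """Default 170° equidistant endoscope camera at 256x256."""
    return pc.CameraModel.for_fov(170.0, "equidistant", width=256, height=256)


@pytest.fixture(scope="session")
def pinhole_camera() -> pc.CameraModel:
    """Narrow pinhole camera used for geometry-oracle scenes."""
    return pc.CameraModel.for_fov(
        60.0, "pinhole", width=512, height=512, fov_fisheye_deg=170.0
    )


@pytest.fixture(scope="session")
def hemisphere_sample(pinhole_camera) -> pc.SceneSample:
    """8 mm sessile hemisphere at 25 mm, centre FOV, pinhole projection."""
    return pc.make_scene_sample(
        pc.PolypSpec(8.0, "sessile", polyp_id="fix"),
        pc.PlacementSpec("center", "medium", depth_mm=25.0),
        pinhole_camera,
        seed=7,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
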