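import numpy as np
import pytest

from avcalc.ct_io import CTVolume, LandmarkSet


def make_volume(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                orientation=None) -> CTVolume:
    """Small helper: wrap an array (or fill a shape) into a CTVolume."""
    values = np.asarray(values, dtype=float)
    if orientation is None:
        orientation = np.eye(3)
    return CTVolume(voxels=values, spacing=np.asarray(spacing),
                    origin=np.asarray(origin), orientation=np.asarray(orientation))


def axial_landmarks(z: float, extent_xy: float = 10.0, ref_offset: float = 10.0) -> LandmarkSet:
    """Landmarks whose annulus plane is z = const, aortic side toward +z."""
    r = extent_xy / 2
    return LandmarkSet(
        nadir_points=np.array([[r, 0.0, z], [0.0, r, z], [-r, -r, z]]),
        aortic_reference=np.array([0.0, 0.0, z + ref_offset]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
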