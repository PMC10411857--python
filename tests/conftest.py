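import numpy as np
import pytest

from polarfish import synthetic_data as sd
from polarfish.stack_io import RoiPolygon

#: unit square, clockwise in the shoelace sense (negative signed area)
SQUARE = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]])


@pytest.fixture
def square_polygon():
    return RoiPolygon(SQUARE.copy())


@pytest.fixture
def square_partition(square_polygon):
    """Four single-edge segments: nuclear, side1, invasive, side2."""
    from polarfish.cell_geometry import snap_anchors
    return snap_anchors(square_polygon, SQUARE.copy())


@pytest.fixture(scope="session")
def tiny_scene():
    """One rendered high-SNR scene, shared across read-only tests."""
    return sd.make_scene(shape=(12, 64, 160), n_spots=(15, 10),
                         polarity_bias=(0.5, 0.0), snr=10.0, seed=42,
                         min_spacing=6.0)


@pytest.fixture(scope="session")
def tiny_scene_mask(tiny_scene):
    return sd.scene_mask(tiny_scene.polygon, tiny_scene.stack.voxels.shape[1:])
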