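import numpy as np
import pytest

from hallerquant import Skeleton, VesselMask, PIXEL_SIZE_MM_DEFAULT
from hallerquant.simulate import VesselSceneParams, generate_vessel_image


def bar_mask(height: int, width: int, bar_rows: slice, bar_cols: slice,
             pixel_size_mm: float = PIXEL_SIZE_MM_DEFAULT) -> VesselMask:
    """Rectangular bar on an empty field."""
    arr = np.zeros((height, width), dtype=bool)
    arr[bar_rows, bar_cols] = True
    return VesselMask(arr, pixel_size_mm)


def skeleton_from_coords(coords, shape, pixel_size_mm=PIXEL_SIZE_MM_DEFAULT) -> Skeleton:
    arr = np.zeros(shape, dtype=bool)
    for r, c in coords:
        arr[r, c] = True
    return Skeleton(arr, pixel_size_mm)


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic scene with its ground truth (session-cached)."""
    params = VesselSceneParams(seed=3)
    image, truth_mask, trunks = generate_vessel_image(params)
    return params, image, truth_mask, trunks
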