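import numpy as np
import pytest

from octa_dcp.simulate import generate_dcp_angiogram, generate_scp_angiogram

PIXEL_MM = 3.0 / 320


@pytest.fixture(scope="session")
def clean_dcp():
    """Default clean deep-plexus angiogram (FAZ radius 0.3 mm, no dropout)."""
    img, truth = generate_dcp_angiogram(seed=11)
    return img, truth


@pytest.fixture(scope="session")
def clean_scp():
    """Default superficial angiogram with 4 major vessels."""
    img, truth = generate_scp_angiogram(seed=12)
    return img, truth


@pytest.fixture(scope="session")
def clean_pair(clean_dcp, clean_scp):
    return clean_dcp[0], clean_scp[0], clean_scp[1]


def full_vessel_map_with_holes(holes, n_px=320, width_mm=3.0):
    """All-vessel binary map with the given (cy_px, cx_px, r_px) disc holes."""
    from octa_dcp.metrics import BinaryVesselMap

    mask = np.ones((n_px, n_px), dtype=bool)
    yy, xx = np.meshgrid(np.arange(n_px), np.arange(n_px), indexing="ij")
    for cy, cx, r in holes:
        mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = False
    return BinaryVesselMap(mask=mask, pixel_size_mm=width_mm / n_px)
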