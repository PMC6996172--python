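"""Large-vessel mask extraction from superficial-plexus angiograms.

The superficial capillary plexus carries the major arterioles and venules;
their caliber well exceeds capillary scale, so a morphological opening at the
expected caliber isolates them from the capillary texture.  The mask is used
both for projection-artifact injection (the SCP shadow pattern) and for the
first step of projection-artifact detection.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.measure import regionprops

from .types import EnfaceAngiogram

__all__ = ["extract_large_vessel_mask"]


def extract_large_vessel_mask(
    scp: EnfaceAngiogram,
    min_caliber_mm: float = 0.04,
    min_length_mm: float = 0.5,
) -> np.ndarray:
    """Boolean mask of large continuous vessels on an SCP image.

    Bright structures are opened with a disk of radius ``min_caliber_mm / 2``
    so only vessels at least that caliber survive, then short residual blobs
    (major axis below ``min_length_mm``) are dropped.
    """
    img = scp.pixels.astype(float)
    psz = scp.pixel_size_mm
    # adaptive cut: large vessels sit well above the capillary texture
    local_mean = ndimage.uniform_filter(img, size=max(3, round(0.25 / psz) | 1))
    bright = img > local_mean + 25
    radius_px = max(1, round(min_caliber_mm / 2 / psz))
    opened = morphology.opening(bright, morphology.disk(radius_px))
    labels, n = ndimage.label(opened, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return opened
    keep = np.zeros(n + 1, dtype=bool)
    min_len_px = min_length_mm / psz
    for prop in regionprops(labels):
        if prop.axis_major_length >= min_len_px:
            keep[prop.label] = True
    return keep[labels]
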