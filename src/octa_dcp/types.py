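"""Core containers for en-face OCT-A images and their ground truth.

An en-face angiogram is a 2-D projection of flow signal over a retinal depth
slab.  The default geometry follows a common swept-source protocol: a
3 mm x 3 mm macular scan sampled at 320 x 320, i.e. 9.375 um per pixel.
Intensities follow the standard OCT-A convention: perfused tissue (vessels)
is bright, non-perfused tissue is dark.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "EnfaceAngiogram",
    "GroundTruth",
    "DcpMetrics",
    "InvalidGeometryError",
]

Layer = Literal["SCP", "DCP"]


class InvalidGeometryError(ValueError):
    """Raised for non-square, empty, or non-positive image geometry."""


@dataclass
class EnfaceAngiogram:
    """One grayscale en-face slab image plus physical scale and metadata.

    Parameters
    ----------
    pixels
        Square ``uint8`` intensity grid, values in [0, 255].
    width_mm
        Physical width of the scan field (square field of view).
    layer
        ``"SCP"`` (superficial plexus: carries the large arterioles/venules)
        or ``"DCP"`` (deep plexus: vortex-like capillary units).
    quality_score
        Device-reported acquisition quality in [0, 100].  For synthetic
        images this is assigned, not computed.
    seg_error
        Metadata flag: the acquisition's B-scan layer segmentation deviated
        from the expected boundary (judged upstream; B-scans are not part of
        this data model).
    """

    pixels: np.ndarray
    width_mm: float = 3.0
    layer: Layer = "DCP"
    quality_score: int = 60
    seg_error: bool = False
    eye_id: str = ""
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise InvalidGeometryError(
                f"pixels must be a square 2-D grid, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1:
            raise InvalidGeometryError("empty image")
        if self.width_mm <= 0:
            raise InvalidGeometryError(f"width_mm must be positive, got {self.width_mm}")
        if not 0 <= self.quality_score <= 100:
            raise ValueError(f"quality_score must lie in [0, 100], got {self.quality_score}")

    @property
    def n_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def pixel_size_mm(self) -> float:
        return self.width_mm / self.n_px

    def mm_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """(y, x) pixel-centre coordinates in mm, fovea (image centre) at origin."""
        n = self.n_px
        axis = (np.arange(n) - (n - 1) / 2.0) * self.pixel_size_mm
        return np.meshgrid(axis, axis, indexing="ij")

    def with_pixels(self, pixels: np.ndarray) -> "EnfaceAngiogram":
        """Copy of this angiogram with a new pixel grid, metadata preserved."""
        return EnfaceAngiogram(
            pixels=pixels,
            width_mm=self.width_mm,
            layer=self.layer,
            quality_score=self.quality_score,
            seg_error=self.seg_error,
            eye_id=self.eye_id,
            subject_id=self.subject_id,
            session_id=self.session_id,
        )


@dataclass
class GroundTruth:
    """What the simulator actually drew, for downstream validation.

    ``faz_area_mm2`` is the true area of the central avascular disc;
    ``dropout_components`` lists injected capillary non-perfusion regions as
    ``(area_mm2, (y_mm, x_mm))`` pairs; ``artifact_labels`` is empty for a
    clean image and only ever grows as artifacts are injected.
    """

    faz_area_mm2: float = 0.0
    dropout_components: list[tuple[float, tuple[float, float]]] = field(default_factory=list)
    artifact_labels: set[str] = field(default_factory=set)
    seed: int = 0
    large_vessel_mask: np.ndarray | None = None
    faz_center_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.faz_area_mm2 < 0:
            raise ValueError("faz_area_mm2 must be non-negative")


@dataclass(frozen=True)
class DcpMetrics:
    """The metric triple for one DCP image.

    faz_area_mm2: area of the foveal avascular zone.
    vd_pct: vessel density, the percentage of the 1-3 mm parafoveal annulus
        not covered by non-perfusion regions (> 0.02 mm2 dark components).
    fd: box-counting fractal dimension of the skeletonized vessel network.
    """

    faz_area_mm2: float
    vd_pct: float
    fd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.vd_pct <= 100.0:
            raise ValueError(f"vd_pct out of [0, 100]: {self.vd_pct}")
        if not 0.0 <= self.fd <= 2.0:
            raise ValueError(f"fd out of [0, 2]: {self.fd}")
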