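"""Automated quality control of en-face DCP angiograms.

Mirrors a reading-centre exclusion protocol for OCT-A images: projection
artifacts (SCP large-vessel shadows appearing in the deep slab), blur,
motion (row discontinuities and residual motion lines), signal loss (dark
row bands from blinks), a low device quality score (< 40), poor foveal
centration, and B-scan segmentation error (an upstream metadata flag).

Each detector returns a continuous score plus a boolean flag at a default
threshold.  The protocol it emulates is a human reader's judgment, so the
thresholds are calibrated on synthetic fixtures and exposed in
:class:`QCThresholds`; only the quality-score cutoff (40) is a hard
protocol constant.  Physical thresholds are expressed in mm or fractions,
never raw pixels, so the detectors are covariant with scan geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops

from .masks import extract_large_vessel_mask
from .metrics import (
    MetricsConfig,
    _center_radius_mm,
    _closed_perfusion,
    binarize,
    preprocess,
)
from .types import EnfaceAngiogram, InvalidGeometryError

__all__ = [
    "QCThresholds",
    "QCReport",
    "detect_projection_artifact",
    "detect_motion_artifact",
    "detect_blur",
    "detect_signal_loss",
    "check_centration",
    "apply_qc",
    "REASON_PRIORITY",
]

# primary_reason follows the reading-centre reporting order
REASON_PRIORITY = (
    "projection",
    "blur",
    "motion",
    "signal_loss",
    "low_quality",
    "off_center",
    "seg_error",
)

QUALITY_SCORE_CUTOFF = 40  # excluded iff strictly below


@dataclass(frozen=True)
class QCThresholds:
    """Decision thresholds of the automated QC detectors.

    Scores are unitless in [0, 1] except the centration offset (mm).
    Defaults are calibrated on synthetic fixtures to separate clean images
    from artifact injections at default magnitudes.
    """

    projection_score: float = 0.50
    blur_score: float = 0.45  # flag when focus score falls BELOW this
    motion_score: float = 0.30
    signal_loss_frac: float = 0.05  # of image height
    dark_row_intensity: float = 15.0  # 8-bit; rows darker than this are "lost"
    centration_offset_mm: float = 0.5
    # projection detector internals
    min_vessel_caliber_mm: float = 0.04
    continuity_norm_mm: float = 0.8


DEFAULT_THRESHOLDS = QCThresholds()


@dataclass
class QCReport:
    """Per-image QC outcome: scores, triggered flags, and the primary reason."""

    scores: dict[str, float] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)
    projection_assessed: bool = True

    @property
    def excluded(self) -> bool:
        return bool(self.flags)

    @property
    def primary_reason(self) -> str | None:
        if not self.flags:
            return None
        for reason in REASON_PRIORITY:
            if reason in self.flags:
                return reason
        return sorted(self.flags)[0]


def _check_pair_geometry(dcp: EnfaceAngiogram, scp: EnfaceAngiogram) -> None:
    if dcp.n_px != scp.n_px or abs(dcp.width_mm - scp.width_mm) > 1e-9:
        raise InvalidGeometryError(
            f"DCP ({dcp.n_px}px/{dcp.width_mm}mm) and SCP "
            f"({scp.n_px}px/{scp.width_mm}mm) geometries differ"
        )


def detect_projection_artifact(
    dcp: EnfaceAngiogram,
    scp: EnfaceAngiogram,
    thresholds: QCThresholds = DEFAULT_THRESHOLDS,
) -> tuple[float, bool]:
    """Two-step projection-artifact score.

    Step 1 (co-localization): extract the SCP large-vessel mask and measure
    how much brighter the DCP is under that mask than over off-mask
    background — true deep capillaries are uncorrelated with the overlying
    arcades, so a clean DCP shows no such co-elevation.

    Step 2 (morphology): binarize the DCP under the mask and measure the
    longest connected structure.  A projected vessel is continuous over
    millimetres, whereas genuine deep texture under the mask breaks into
    vortex-unit fragments.

    The score is the geometric mean of both evidences, in [0, 1].
    """
    _check_pair_geometry(dcp, scp)
    mask = extract_large_vessel_mask(scp, thresholds.min_vessel_caliber_mm)
    if mask.sum() < 25:  # no large vessels to project
        return 0.0, False
    img = dcp.pixels.astype(float)
    # local background: a ring just outside the mask, so remote defects
    # (e.g. a signal-loss band elsewhere) cannot fake a contrast
    ring_px = max(3, round(0.1 / dcp.pixel_size_mm))
    ring = ndimage.binary_dilation(mask, iterations=ring_px) & ~mask
    m1 = np.median(img[mask])
    m0 = np.median(img[ring])
    co_elevation = float(np.clip((m1 - m0) / 64.0, 0.0, 1.0))

    vessel = binarize(preprocess(dcp)).mask & mask
    labels, n = ndimage.label(vessel, structure=np.ones((3, 3), int))
    longest_mm = 0.0
    if n:
        longest_px = max(p.axis_major_length for p in regionprops(labels))
        longest_mm = longest_px * dcp.pixel_size_mm
    continuity = float(np.clip(longest_mm / thresholds.continuity_norm_mm, 0.0, 1.0))

    score = float(np.sqrt(co_elevation * continuity))
    return score, score > thresholds.projection_score


def detect_motion_artifact(
    img: EnfaceAngiogram,
    thresholds: QCThresholds = DEFAULT_THRESHOLDS,
    max_shift_px: int = 16,
) -> tuple[float, bool]:
    """Motion score from row-to-row misregistration and bright residual
    motion lines.

    For every adjacent row pair the normalized cross-correlation is
    evaluated over lateral lags up to ``max_shift_px``.  In a clean scan
    (or one shifted globally, which is not a discontinuity) neighbouring
    rows correlate best at lag 0; a motion event shows as a pair whose
    correlation peaks at a non-zero lag by a clear margin, and/or as a
    saturated residual line.  The score is the largest correlation margin
    ``corr(best non-zero lag) - corr(0)``, combined with the line evidence.
    """
    px = img.pixels.astype(float)
    rows = px - px.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rows, axis=1)
    margin = 0.0
    for i in range(rows.shape[0] - 1):
        if norms[i] < 1e-6 or norms[i + 1] < 1e-6:
            continue
        corr = np.correlate(rows[i], rows[i + 1], mode="full") / (norms[i] * norms[i + 1])
        lags = np.arange(-rows.shape[1] + 1, rows.shape[1])
        window = np.abs(lags) <= max_shift_px
        c = corr[window]
        lag = lags[window]
        c0 = c[lag == 0][0]
        away = np.abs(lag) >= 2  # ignore sub-pixel jitter
        margin = max(margin, float(c[away].max() - c0))
    shift_score = float(np.clip(margin / 0.5, 0.0, 1.0))

    row_means = px.mean(axis=1)
    line_score = float(np.clip((row_means.max() - 180.0) / 75.0, 0.0, 1.0))

    score = max(shift_score, line_score)
    return score, score > thresholds.motion_score


def detect_blur(
    img: EnfaceAngiogram, thresholds: QCThresholds = DEFAULT_THRESHOLDS
) -> tuple[float, bool]:
    """Focus score: high-frequency energy normalized by image contrast.

    score = RMS of the Laplacian response / image standard deviation, an
    intensity-scale-invariant sharpness measure.  Low score = blurry; a
    constant image scores 0 and is flagged.
    """
    px = img.pixels.astype(float)
    sd = px.std()
    if sd < 1e-9:
        return 0.0, True
    lap = ndimage.laplace(px)
    score = float(np.sqrt(np.mean(lap**2)) / sd)
    return score, score < thresholds.blur_score


def detect_signal_loss(
    img: EnfaceAngiogram, thresholds: QCThresholds = DEFAULT_THRESHOLDS
) -> tuple[float, bool]:
    """Signal-loss score: longest run of dark rows as a fraction of height.

    A blink suppresses the OCT-A signal over a contiguous band of B-scan
    rows; rows whose mean intensity falls below ``dark_row_intensity``
    count as lost.
    """
    row_means = img.pixels.astype(float).mean(axis=1)
    dark = row_means < thresholds.dark_row_intensity
    longest = run = 0
    for d in dark:
        run = run + 1 if d else 0
        longest = max(longest, run)
    score = longest / img.n_px
    return score, score > thresholds.signal_loss_frac


def check_centration(
    dcp: EnfaceAngiogram,
    thresholds: QCThresholds = DEFAULT_THRESHOLDS,
    config: MetricsConfig | None = None,
) -> tuple[float, bool]:
    """Distance (mm) from the detected FAZ centroid to the image centre.

    The FAZ is taken as the largest avascular (dark, closed-map) component
    intersecting the central search disc; flagged when the centroid offset
    strictly exceeds the threshold (default 0.5 mm).  If no region of at
    least FAZ scale (0.03 mm^2) is detectable the fovea is treated as
    off-centre (flagged, offset = inf).
    """
    config = config or MetricsConfig()
    search_mm = thresholds.centration_offset_mm + 0.7
    min_faz_mm2 = 0.03
    bin_map = binarize(preprocess(dcp), config)
    closed = _closed_perfusion(bin_map, config)
    if closed.mean() < 0.05:  # no vascular texture: fovea undetectable
        return float("inf"), True
    labels, n_comp = ndimage.label(~closed, structure=np.ones((3, 3), int))
    if n_comp == 0:
        return float("inf"), True
    r_mm = _center_radius_mm(bin_map)
    near_labels = np.unique(labels[(r_mm <= search_mm) & (labels > 0)])
    px_area = bin_map.pixel_size_mm**2
    sizes = np.bincount(labels.ravel())
    near_labels = [lab for lab in near_labels if sizes[lab] * px_area >= min_faz_mm2]
    if not near_labels:
        return float("inf"), True
    best = max(near_labels, key=lambda lab: sizes[lab])
    ys, xs = np.nonzero(labels == best)
    c = (dcp.n_px - 1) / 2.0
    offset_mm = float(np.hypot(ys.mean() - c, xs.mean() - c) * dcp.pixel_size_mm)
    return offset_mm, offset_mm > thresholds.centration_offset_mm


def apply_qc(
    dcp: EnfaceAngiogram,
    scp: EnfaceAngiogram | None,
    metadata: dict | None = None,
    thresholds: QCThresholds = DEFAULT_THRESHOLDS,
) -> QCReport:
    """Run all detectors and assemble the exclusion decision.

    ``low_quality`` triggers iff the device quality score is strictly below
    40; ``seg_error`` is copied from metadata (B-scans are judged
    upstream).  Without an SCP image the projection check is reported as
    not assessed — the image is not auto-passed, the remaining checks still
    apply.  Flags are the union of detector flags; the primary reason
    follows a fixed priority order.
    """
    metadata = metadata or {}
    report = QCReport()

    if scp is not None:
        score, flagged = detect_projection_artifact(dcp, scp, thresholds)
        report.scores["projection"] = score
        if flagged:
            report.flags.add("projection")
    else:
        report.projection_assessed = False

    for name, detector in (
        ("blur", detect_blur),
        ("motion", detect_motion_artifact),
        ("signal_loss", detect_signal_loss),
    ):
        score, flagged = detector(dcp, thresholds)
        report.scores[name] = score
        if flagged:
            report.flags.add(name)

    offset, flagged = check_centration(dcp, thresholds)
    report.scores["off_center"] = offset
    if flagged:
        report.flags.add("off_center")

    quality = metadata.get("quality_score", dcp.quality_score)
    report.scores["quality_score"] = float(quality)
    if quality < QUALITY_SCORE_CUTOFF:
        report.flags.add("low_quality")

    if metadata.get("seg_error", dcp.seg_error):
        report.flags.add("seg_error")

    return report
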