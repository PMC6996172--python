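"""Synthetic en-face OCT-A angiograms with known ground truth.

The deep capillary plexus (DCP) is emulated as a tiling of polygonal
(Voronoi-like) units whose capillaries converge radially on a central
epicenter — the "vortex" arrangement characteristic of the deep plexus —
with a capillary ring delimiting a central avascular disc (the FAZ) and
optional dark non-perfusion (dropout) regions.  The superficial plexus (SCP)
is emulated as a few smoothly curving large-caliber vessels over a fine
capillary web.  Four acquisition artifacts can be injected on top of a clean
image: projection of the SCP large-vessel shadow, motion (row-block
discontinuities plus a bright residual line), blur, and signal loss
(a near-zero row band, as after a blink).

Every generator is a pure function of (parameters, seed): identical calls
return bit-identical images.  There is no physical OCT signal model here —
the textures are geometric stand-ins whose value is that their ground truth
(FAZ area, dropout areas, large-vessel masks, artifact labels) is known
exactly.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import dilation, disk

from .masks import extract_large_vessel_mask
from .types import EnfaceAngiogram, GroundTruth, InvalidGeometryError

__all__ = [
    "generate_dcp_angiogram",
    "generate_scp_angiogram",
    "inject_artifact",
    "ARTIFACT_KINDS",
    "MissingInputError",
]

ARTIFACT_KINDS = ("projection", "motion", "blur", "signal_loss")

# intensity levels (8-bit): background tissue vs perfused vessel
_BG_LEVEL = 30.0
_VESSEL_LEVEL = 200.0
_SCP_MAJOR_LEVEL = 230.0


class MissingInputError(ValueError):
    """An artifact injector was not given a required auxiliary input."""


def _render(vessel: np.ndarray, rng: np.random.Generator, noise_sd: float,
            vessel_level: float = _VESSEL_LEVEL, smooth_px: float = 0.6) -> np.ndarray:
    """Rasterize a boolean vessel map to a noisy 8-bit angiogram."""
    img = np.where(vessel, vessel_level, _BG_LEVEL).astype(float)
    if smooth_px > 0:
        img = ndimage.gaussian_filter(img, smooth_px)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def _vortex_vessels(
    yy: np.ndarray,
    xx: np.ndarray,
    rng: np.random.Generator,
    vortex_density: float,
    width_mm: float,
    caliber_mm: float,
    swirl: float,
) -> np.ndarray:
    """Capillary map: polygonal unit borders + spokes converging on epicenters."""
    spacing = 1.0 / np.sqrt(vortex_density)
    half = width_mm / 2 + spacing  # pad so border cells are complete
    grid = np.arange(-half, half, spacing)
    cy, cx = np.meshgrid(grid, grid, indexing="ij")
    centers = np.column_stack([cy.ravel(), cx.ravel()])
    centers = centers + rng.uniform(-0.35 * spacing, 0.35 * spacing, centers.shape)

    tree = cKDTree(centers)
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    dist, idx = tree.query(pts, k=2)
    d1 = dist[:, 0].reshape(yy.shape)
    d2 = dist[:, 1].reshape(yy.shape)
    nearest = idx[:, 0].reshape(yy.shape)

    # polygonal unit outlines: ridge of the nearest-epicenter partition
    edges = (d2 - d1) < caliber_mm

    # spokes: per cell, k capillaries at random phase converging on the epicenter
    n_cells = len(centers)
    k_spokes = rng.integers(6, 10, n_cells)
    phases = rng.uniform(0, 2 * np.pi, n_cells)
    dy = yy - centers[nearest, 0]
    dx = xx - centers[nearest, 1]
    r = d1
    theta = np.arctan2(dy, dx) + swirl * (r / spacing)  # swirl bends spokes
    k = k_spokes[nearest]
    # angular offset to the nearest of the k spoke directions
    delta = np.mod(theta * k - phases[nearest] + np.pi, 2 * np.pi) - np.pi
    perp = r * np.abs(np.sin(delta / k))  # perpendicular distance to spoke line
    spokes = perp < caliber_mm / 2
    return edges | spokes


def generate_dcp_angiogram(
    faz_radius_mm: float = 0.3,
    vortex_density: float = 45.0,
    dropout_spec: list[tuple[float, float, float]] | None = None,
    noise_sd: float = 6.0,
    faz_center_mm: tuple[float, float] = (0.0, 0.0),
    n_px: int = 320,
    width_mm: float = 3.0,
    caliber_mm: float = 0.015,
    swirl: float = 0.5,
    quality_score: int = 60,
    seed: int = 0,
    noise_seed: int | None = None,
    **metadata: str,
) -> tuple[EnfaceAngiogram, GroundTruth]:
    """Generate a clean deep-plexus angiogram and its ground truth.

    Parameters
    ----------
    faz_radius_mm
        Radius of the central avascular disc; a capillary ring is drawn just
        outside it, so the avascular area is exactly ``pi * r**2``.
    vortex_density
        Vortex epicenters per mm^2 (cell spacing ~ ``1/sqrt(density)``).
    dropout_spec
        Non-perfusion regions as ``(y_mm, x_mm, radius_mm)`` discs.  They
        must not overlap the FAZ disc.
    noise_sd
        Additive Gaussian intensity noise (8-bit scale).
    faz_center_mm
        Fovea position; non-zero values emulate poor centration.
    noise_seed
        When given, acquisition noise is drawn from its own stream while
        the vasculature stays tied to ``seed`` — two calls with the same
        ``seed`` and different ``noise_seed`` emulate scanning the same
        eye twice (test-retest).
    """
    if n_px <= 0 or width_mm <= 0:
        raise InvalidGeometryError("n_px and width_mm must be positive")
    if not 0 <= faz_radius_mm < width_mm / 2:
        raise ValueError(f"faz_radius_mm must lie in [0, width/2): {faz_radius_mm}")
    dropout_spec = list(dropout_spec or [])

    fy, fx = faz_center_mm
    for (dy0, dx0, dr) in dropout_spec:
        if dr <= 0:
            raise ValueError("dropout radius must be positive")
        if np.hypot(dy0 - fy, dx0 - fx) < dr + faz_radius_mm:
            raise ValueError("dropout region overlaps the FAZ")

    rng = np.random.default_rng(seed)
    axis = (np.arange(n_px) - (n_px - 1) / 2.0) * (width_mm / n_px)
    yy, xx = np.meshgrid(axis, axis, indexing="ij")

    vessel = _vortex_vessels(yy, xx, rng, vortex_density, width_mm, caliber_mm, swirl)

    r_fovea = np.hypot(yy - fy, xx - fx)
    if faz_radius_mm > 0:
        # clear the avascular disc, then draw the bordering capillary ring
        vessel &= r_fovea >= faz_radius_mm
        ring = (r_fovea >= faz_radius_mm) & (r_fovea < faz_radius_mm + 1.5 * caliber_mm)
        vessel |= ring

    for (dy0, dx0, dr) in dropout_spec:
        vessel &= np.hypot(yy - dy0, xx - dx0) >= dr

    noise_rng = rng if noise_seed is None else np.random.default_rng(noise_seed)
    pixels = _render(vessel, noise_rng, noise_sd)
    img = EnfaceAngiogram(
        pixels=pixels, width_mm=width_mm, layer="DCP",
        quality_score=quality_score, **metadata,
    )
    truth = GroundTruth(
        faz_area_mm2=np.pi * faz_radius_mm**2,
        dropout_components=[
            (np.pi * dr**2, (dy0, dx0)) for (dy0, dx0, dr) in dropout_spec
        ],
        seed=seed,
        faz_center_mm=faz_center_mm,
    )
    return img, truth


def generate_scp_angiogram(
    n_major_vessels: int = 4,
    vessel_caliber_px: int = 6,
    faz_radius_mm: float = 0.3,
    noise_sd: float = 6.0,
    n_px: int = 320,
    width_mm: float = 3.0,
    quality_score: int = 60,
    seed: int = 0,
    **metadata: str,
) -> tuple[EnfaceAngiogram, GroundTruth]:
    """Generate a superficial-plexus angiogram: large vessels over a fine web.

    The major vessels are smoothly wobbling curves spanning the field in
    well-separated lanes (so their masks stay disjoint), avoiding the foveal
    center.  Ground truth stores the large-vessel mask.
    """
    if n_major_vessels < 0:
        raise ValueError("n_major_vessels must be >= 0")
    if vessel_caliber_px >= n_px:
        raise InvalidGeometryError("vessel caliber exceeds image size")
    if n_px <= 0 or width_mm <= 0:
        raise InvalidGeometryError("n_px and width_mm must be positive")

    rng = np.random.default_rng(seed)

    # fine capillary web: thresholded band-passed noise
    field = ndimage.gaussian_filter(rng.normal(size=(n_px, n_px)), 1.2)
    web = field > np.quantile(field, 0.62)

    major = np.zeros((n_px, n_px), dtype=bool)
    if n_major_vessels > 0:
        horizontal = bool(rng.integers(0, 2))
        # evenly spread lanes over two side bands, skipping the foveal band,
        # with gaps wide enough that wobbling vessels stay disjoint
        s = (np.arange(n_major_vessels) + 0.5) / n_major_vessels * 0.72
        lanes = np.where(s < 0.36, 0.08 + s, 0.56 + (s - 0.36)) * n_px
        lane_gap = 0.72 * n_px / max(1, n_major_vessels)
        wobble_amp = min(0.25 * lane_gap - vessel_caliber_px, 0.04 * n_px)
        wobble_amp = max(wobble_amp, 0.0)
        t = np.linspace(0, 1, 4 * n_px)
        along = t * (n_px - 1)
        for lane in lanes:
            freq = rng.uniform(1.0, 2.5)
            phase = rng.uniform(0, 2 * np.pi)
            across = lane + wobble_amp * np.sin(2 * np.pi * freq * t + phase)
            rows = np.clip(np.round(across if horizontal else along), 0, n_px - 1).astype(int)
            cols = np.clip(np.round(along if horizontal else across), 0, n_px - 1).astype(int)
            path = np.zeros((n_px, n_px), dtype=bool)
            path[rows, cols] = True
            major |= dilation(path, disk(max(1, vessel_caliber_px // 2)))

    axis = (np.arange(n_px) - (n_px - 1) / 2.0) * (width_mm / n_px)
    yy, xx = np.meshgrid(axis, axis, indexing="ij")
    r = np.hypot(yy, xx)
    web &= r >= faz_radius_mm

    img_f = np.full((n_px, n_px), _BG_LEVEL)
    img_f[web] = 140.0
    img_f[major] = _SCP_MAJOR_LEVEL
    img_f = ndimage.gaussian_filter(img_f, 0.6)
    img_f = img_f + rng.normal(0.0, noise_sd, img_f.shape)
    pixels = np.clip(img_f, 0, 255).astype(np.uint8)

    img = EnfaceAngiogram(
        pixels=pixels, width_mm=width_mm, layer="SCP",
        quality_score=quality_score, **metadata,
    )
    truth = GroundTruth(
        faz_area_mm2=np.pi * faz_radius_mm**2,
        seed=seed,
        large_vessel_mask=major,
    )
    return img, truth


def inject_artifact(
    image: EnfaceAngiogram,
    kind: str,
    magnitude: float,
    aux: EnfaceAngiogram | None = None,
    aux_mask: np.ndarray | None = None,
    truth: GroundTruth | None = None,
) -> EnfaceAngiogram:
    """Overlay one acquisition artifact on an angiogram.

    kind / magnitude semantics:

    - ``projection``: opacity in [0, 1] of the SCP large-vessel shadow;
      requires ``aux`` (the paired SCP image).  Intensities under the
      large-vessel mask only ever increase toward the SCP values.
    - ``motion``: lateral shift in pixels applied to two row blocks, with a
      saturated residual motion line at each block boundary.
    - ``blur``: isotropic Gaussian smoothing, sigma = magnitude pixels.
    - ``signal_loss``: a contiguous band of ``round(magnitude)`` rows set to
      near-zero intensity (as after a blink).

    ``magnitude == 0`` returns a bit-identical copy.  If ``truth`` is given,
    the artifact label is appended to it.
    """
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}; expected one of {ARTIFACT_KINDS}")
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")

    px = image.pixels.copy()
    if magnitude > 0:
        if kind == "projection":
            if aux is None:
                raise MissingInputError("projection injection requires the paired SCP image")
            if aux.pixels.shape != px.shape:
                raise InvalidGeometryError("SCP/DCP geometry mismatch")
            mask = aux_mask if aux_mask is not None else extract_large_vessel_mask(aux)
            m = min(float(magnitude), 1.0)
            lift = np.clip(aux.pixels.astype(float) - px, 0, None)
            out = px.astype(float)
            out[mask] += m * lift[mask]
            px = np.clip(out, 0, 255).astype(np.uint8)
        elif kind == "motion":
            n = px.shape[0]
            shift = int(round(magnitude))
            block = max(4, n // 20)
            for frac, sgn in ((0.35, 1), (0.65, -1)):
                top = int(frac * n)
                px[top : top + block] = np.roll(px[top : top + block], sgn * shift, axis=1)
                px[top] = 255  # residual motion line
        elif kind == "blur":
            px = np.clip(
                ndimage.gaussian_filter(px.astype(float), float(magnitude)), 0, 255
            ).astype(np.uint8)
        elif kind == "signal_loss":
            n = px.shape[0]
            band = min(n, int(round(magnitude)))
            top = max(0, int(0.55 * n) - band // 2)
            px[top : top + band] = 2
    out_img = image.with_pixels(px)
    if truth is not None and magnitude > 0:
        truth.artifact_labels.add(kind)
    return out_img
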