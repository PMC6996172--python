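"""Reading and writing angiograms, sidecar metadata and tables.

Images are stored as single-channel 8-bit PNG (or TIFF), each with a JSON
sidecar (same stem, ``.json``) carrying the physical scale, layer, device
quality score, segmentation-error flag, identifiers, and — for synthetic
images — the ground-truth artifact labels.  Cohorts and metric tables are
plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .types import EnfaceAngiogram, GroundTruth

__all__ = ["save_angiogram", "load_angiogram"]


def save_angiogram(
    img: EnfaceAngiogram, path: str | Path, truth: GroundTruth | None = None
) -> Path:
    """Write the image and its JSON sidecar; returns the image path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, img.pixels.astype(np.uint8))
    meta = {
        "width_mm": img.width_mm,
        "n_px": img.n_px,
        "layer": img.layer,
        "quality_score": img.quality_score,
        "seg_error": img.seg_error,
        "eye_id": img.eye_id,
        "subject_id": img.subject_id,
        "session_id": img.session_id,
    }
    if truth is not None:
        meta["artifact_labels"] = sorted(truth.artifact_labels)
        meta["true_faz_area_mm2"] = truth.faz_area_mm2
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def load_angiogram(path: str | Path) -> EnfaceAngiogram:
    """Read an image and its JSON sidecar back into an angiogram."""
    path = Path(path)
    pixels = np.asarray(iio.imread(path))
    if pixels.ndim == 3:  # tolerate grayscale saved with a channel axis
        pixels = pixels[..., 0]
    meta = json.loads(path.with_suffix(".json").read_text())
    return EnfaceAngiogram(
        pixels=pixels.astype(np.uint8),
        width_mm=float(meta.get("width_mm", 3.0)),
        layer=meta.get("layer", "DCP"),
        quality_score=int(meta.get("quality_score", 60)),
        seg_error=bool(meta.get("seg_error", False)),
        eye_id=meta.get("eye_id", ""),
        subject_id=meta.get("subject_id", ""),
        session_id=meta.get("session_id", ""),
    )
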