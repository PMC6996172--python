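#!/usr/bin/env python
"""Generate the synthetic imaging batch driving the downstream analyses.

Creates paired SCP/DCP en-face angiograms for a batch of eyes, injects the
four artifact classes (projection, blur, motion, signal loss) plus a
low-quality-score eye and an off-centre fovea into a known subset, and
writes the images (PNG + JSON sidecars) together with a manifest CSV that
records the injected ground truth.

Images are binary, so they go under scratch/; the manifest and ground
truth go under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from octa_dcp.io import save_angiogram
from octa_dcp.simulate import (
    generate_dcp_angiogram,
    generate_scp_angiogram,
    inject_artifact,
)

MAGNITUDES = {"projection": 1.0, "blur": 3.0, "motion": 8.0, "signal_loss": 40.0}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=24, help="eyes to simulate")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("scratch/angiograms"))
    ap.add_argument("--manifest", type=Path, default=Path("results/manifest.csv"))
    args = ap.parse_args()

    kinds = list(MAGNITUDES)
    rows = []
    for i in range(args.n):
        eye = f"S{i:03d}_OD"
        dcp_kwargs = {}
        quality = 60
        # every 3rd eye gets a defect, cycling through the taxonomy
        defect = None
        if i % 3 == 0:
            defect = (kinds + ["low_quality", "off_center"])[(i // 3) % 6]
            if defect == "low_quality":
                quality = 35
            elif defect == "off_center":
                dcp_kwargs["faz_center_mm"] = (0.0, 0.9)

        dcp, truth = generate_dcp_angiogram(
            seed=args.seed * 100 + i, quality_score=quality,
            eye_id=eye, subject_id=eye[:4], **dcp_kwargs,
        )
        scp, scp_truth = generate_scp_angiogram(
            seed=args.seed * 100 + 50_000 + i, eye_id=eye, subject_id=eye[:4],
        )
        if defect in MAGNITUDES:
            dcp = inject_artifact(
                dcp, defect, MAGNITUDES[defect],
                aux=scp, aux_mask=scp_truth.large_vessel_mask, truth=truth,
            )

        dcp_path = save_angiogram(dcp, args.out / f"{eye}_dcp.png", truth=truth)
        scp_path = save_angiogram(scp, args.out / f"{eye}_scp.png")
        rows.append(
            {
                "eye_id": eye,
                "dcp_path": str(dcp_path),
                "scp_path": str(scp_path),
                "injected_defect": defect or "",
                "quality_score": quality,
                "true_faz_area_mm2": truth.faz_area_mm2,
            }
        )

    manifest = pd.DataFrame(rows)
    args.manifest.parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(args.manifest, index=False)
    n_defect = (manifest.injected_defect != "").sum()
    print(f"wrote {len(manifest)} eyes ({n_defect} with injected defects) -> {args.manifest}")


if __name__ == "__main__":
    main()
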