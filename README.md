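# octa-dcp

Artifact-aware quantification of the **deep capillary plexus (DCP)** on
en-face OCT angiography, built for studying diabetic macular ischemia.

OCT-A resolves the retinal vasculature into layers, and in diabetes the
deep plexus is damaged earlier and harder than the superficial one — but
its en-face images are plagued by artifacts, above all *projection* of the
overlying superficial vessels into the deep slab. This package provides
the full analysis chain such a study needs, exercised end-to-end on
synthetic data with exact ground truth:

- **`octa_dcp.simulate` / `octa_dcp.cohort`** — synthetic en-face
  angiograms (vortex-textured deep plexus with a true FAZ, large-vessel
  superficial plexus, four injectable artifact classes) and synthetic
  eye-level cohorts with configurable effect sizes and fellow-eye
  correlation;
- **`octa_dcp.qc`** — automated analogues of a reading-centre exclusion
  protocol: projection, blur, motion, signal loss, low quality score
  (< 40), poor centration, segmentation-error metadata; per-image scores,
  flags and a primary exclusion reason;
- **`octa_dcp.metrics`** — the metric triple per image:
  FAZ area (mm², exact pixel-count rule), vessel density (% of the
  1–3 mm parafoveal annulus free of non-perfusion, where a dark component
  qualifies iff its area exceeds 0.02 mm²), and the box-counting fractal
  dimension of the skeletonized network;
- **`octa_dcp.reliability`** — ICC(2,1) with F-based 95% CI for
  intra-/inter-session repeatability;
- **`octa_dcp.association`** — the statistical workflow: per-SD
  standardization, univariate GEE screen, multivariable GEE
  (identity link, subject clusters, exchangeable working correlation,
  robust SEs), and the DME-excluded sensitivity repeat.

The core model for associations is the marginal linear model

    E[y_ij] = β0 + Σ_k β_k z_ijk ,   Cov within subject: exchangeable,

fitted by generalized estimating equations with sandwich standard errors,
where `y` is a DCP metric for eye `j` of subject `i` and `z` are
standardized predictors (DR severity as dummies vs no DR). See
`docs/methods.md` for all modelling choices and defaults.

## Worked example

```python
from octa_dcp import (generate_dcp_angiogram, generate_scp_angiogram,
                      inject_artifact, apply_qc, quantify)

dcp, truth = generate_dcp_angiogram(faz_radius_mm=0.3, seed=11)
scp, scp_truth = generate_scp_angiogram(seed=12)

print(apply_qc(dcp, scp).excluded)        # False  (clean pair passes QC)
bad = inject_artifact(dcp, "projection", 1.0, aux=scp,
                      aux_mask=scp_truth.large_vessel_mask)
print(apply_qc(bad, scp).primary_reason)  # 'projection'

m = quantify(dcp)
print(f"FAZ {m.faz_area_mm2:.4f} mm2 (true {truth.faz_area_mm2:.4f}), "
      f"VD {m.vd_pct:.1f}%, FD {m.fd:.3f}")
# FAZ 0.2830 mm2 (true 0.2827), VD 100.0%, FD 1.884
```

The measured FAZ area agrees with the generated ground truth to ~0.1%,
the clean parafoveal annulus is fully perfused (VD 100%), and the dense
synthetic capillary mesh has a box-counting dimension near 1.9.

The numbered scripts under `analysis/` run the same chain as a narrative
pipeline — simulate a batch (`01`), QC it (`02`, the confusion matrix of
automated reasons vs injected defects is diagonal), quantify the passing
eyes (`03`), estimate test-retest ICCs on simulated re-scans (`04`), and
fit the association models on a synthetic cohort (`05`) — writing their
tables under `results/`.

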