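# Methods

This package re-implements, as tested and reusable code, an analysis chain
for the deep capillary plexus (DCP) on en-face OCT angiography: synthetic
data generation with known ground truth, automated image quality control,
quantification (FAZ area, vessel density, fractal dimension), test-retest
reliability, and clustered association models. Because no patient images or
records are available, every stage is exercised on synthetic inputs whose
ground truth is exact; this note records the models, defaults, and the
design decisions taken where the protocol being modelled is qualitative.

## Synthetic angiograms

**Deep plexus.** The DCP texture is a tiling of polygonal (Voronoi-like)
units: epicenters are laid on a jittered grid at `vortex_density` (default
45 /mm², cell spacing ≈ 0.15 mm); capillaries are the ridges of the
nearest-epicenter partition plus 6–9 spokes per cell converging radially on
the epicenter with a mild angular swirl — the "vortex" arrangement that
distinguishes genuine deep-plexus texture from projected superficial
vessels. A capillary ring is drawn just outside the avascular disc of
radius `faz_radius_mm` (default 0.3 mm), so the true FAZ area is exactly
πr². Optional dropout discs (capillary non-perfusion) are cleared of
vessels; they may not overlap the FAZ. Rendering uses the standard en-face
convention (vessels bright): background 30, vessels 200 on the 8-bit scale,
0.6 px Gaussian optics blur, additive Gaussian noise (default SD 6).
Default geometry is 320 × 320 px over 3 × 3 mm (9.375 µm/px). Capillary
caliber defaults to 0.015 mm, chosen together with the default density so
that a clean image contains no inter-capillary gap above the 0.02 mm²
non-perfusion cutoff — clean images are fully perfused by construction.

**Superficial plexus.** A fine thresholded band-passed-noise capillary web
plus `n_major_vessels` (default 4) smoothly wobbling large vessels
(default caliber 6 px) routed in separated lanes that avoid the fovea, so
their masks are disjoint and elongated. The ground truth stores the
large-vessel mask used by projection injection and detection tests.

**Artifacts.** Injectors are pure functions; magnitude 0 is a bit-exact
identity, and labels only ever accumulate on the ground truth:

- *projection* — under the SCP large-vessel mask, intensities are raised
  toward the SCP values by opacity `magnitude` (monotone: never below the
  input);
- *motion* — two row blocks are shifted laterally by `magnitude` px with a
  saturated residual line at each boundary;
- *blur* — Gaussian smoothing, σ = `magnitude` px;
- *signal loss* — a band of `round(magnitude)` rows set to near zero, as
  after a blink.

A separate `noise_seed` lets the same vasculature be "re-scanned" with
fresh acquisition noise, which is how the repeatability study is built.

**What the generator does not emulate:** no physical OCT signal model, no
B-scans or flow simulation, no media opacities, no biological inter-visit
change, and no quantitative match to real DCP texture statistics (none are
published at this granularity). Passing recovery tests therefore shows the
measurement chain is faithful to known geometry — not that it is validated
on patient data.

## Quality control

The QC battery emulates a reading-centre exclusion protocol whose criteria
are qualitative except for the device quality score (< 40 excludes, strict).
All thresholds live in `QCThresholds` and were calibrated once on synthetic
fixture batches; physical quantities are expressed in mm or fractions so
detectors are covariant with scan geometry.

- **Projection** (two steps, mirroring how a reader compares the paired
  images): (1) co-localization — the SCP large-vessel mask is extracted by
  opening at ≥ 0.04 mm caliber, and the DCP median intensity under the mask
  is compared with a dilation ring just outside it (a local background, so
  remote defects cannot fake contrast); (2) morphology — the binarized DCP
  restricted to the mask is measured for its longest connected component:
  a projected vessel is continuous over ~1 mm, vortex fragments are not.
  Score = geometric mean, flag > 0.50. On fixture batches clean pairs score
  ≤ ~0.2 and full-opacity projections 1.0.
- **Motion**: for every adjacent row pair, normalized cross-correlation
  over lags ≤ 16 px; the score is the largest margin by which a non-zero
  lag beats lag 0 (plus saturated-line evidence). A global shift of the
  whole image leaves all pairs aligned and scores 0 — only discontinuity
  counts. Flag > 0.30.
- **Blur**: RMS Laplacian over image SD (intensity-scale invariant focus
  measure); flag < 0.45. A constant image scores 0 and is flagged.
- **Signal loss**: longest run of rows with mean intensity < 15, as a
  fraction of height; flag > 0.05 (16 of 320 rows).
- **Centration**: the largest avascular component (≥ 0.03 mm²) near the
  centre is the FAZ; flagged when its centroid is strictly more than
  0.5 mm off centre, or when no such component exists.
- **Quality score** (< 40, strict) and **segmentation error** are metadata
  rules; B-scans are not part of the data model, so segmentation error is
  an upstream flag.

`apply_qc` unions all flags (no detector can clear another's) and assigns
the primary reason by the fixed priority projection > blur > motion >
signal loss > low quality > off centre > segmentation error, following the
reporting order of the protocol being modelled. Whether a single reason
sufficed historically when several co-occurred is unknowable from a
reported tally; the priority order is this package's convention. A missing
SCP image leaves the projection check "not assessed" without auto-passing
the eye.

## Quantification

- **Preprocessing**: bilateral filter (spatial σ = `denoise_strength`,
  default 1 px; range σ fixed at 8% of the intensity scale). Strength 0 is
  the identity. Chosen because it provably reduces error to the clean
  image on noisy fixtures while preserving capillary edges.
- **Binarization**: vessel iff brighter than the local mean (0.25 mm
  window) by an offset of 10 grey levels. Exactly invariant to uniform
  intensity offsets; a constant image maps to all-background. The method
  behind the modelled protocol is unspecified, so this is a deliberate,
  configurable choice.
- **FAZ**: the binary map is closed with a disk at capillary scale
  (0.03 mm; 0 disables) so normal inter-capillary gaps cannot leak into
  the zone; the FAZ is the non-vessel component containing the image
  centre (or nearest within the central 1-mm circle). Area is exactly
  pixel count × pixel area — no boundary smoothing. Whether the original
  program used flood fill or contour tracing is unstated; closing-then-
  component is this package's rule.
- **Vessel density**: dark components of the closed map qualify as
  non-perfusion by *total* area strictly greater than 0.02 mm² (computed
  in mm², avoiding pixel-rounding dialects); VD = 100 × (annulus −
  annulus ∩ non-perfusion)/annulus over the parafoveal annulus (outer
  diameter 3 mm, inner 1 mm, pixel centres). A component partially inside
  the annulus is classified by its total area but only its overlap is
  subtracted. The FAZ is not exempted: it normally lies inside the inner
  disc, but if it crossed the 0.5 mm radius its overlap would count. The
  implementation agrees with a brute-force per-pixel oracle to one
  pixel-area on all fixtures.
- **Skeleton and fractal dimension**: topology-preserving thinning, then
  box counting over a dyadic ladder (2 px up to n/4); FD = −slope of the
  log-log least-squares fit. The ladder and fit range are configurable.
  Analytic checks: a line gives 1.0, the filled grid 2.0, a depth-8
  Sierpinski gasket log 3/log 2 within 0.05.
- No axial-length magnification correction is applied (the protocol being
  modelled deliberately omitted it, its validation not covering the deep
  plexus).

## Reliability

`compute_icc` wraps the two-way random-effects, absolute-agreement,
single-measure ICC(2,1) — standard for test-retest of one device — with the
F-based 95% CI; ICC(2,k) is available via `measure="average"` since the
single-vs-average choice in comparable reports is often unstated. Exact
duplicate scans give exactly 1; simulated variance components (3, 1) at
n = 200 recover 0.75 within 0.05. Fewer than 5 complete pairs, or zero
total variance, raise typed errors. On noise-only synthetic re-scans the
pipeline's ICCs are ≈ 1: they bound the software's own contribution to
measurement variance and must not be read as emulating clinical
repeatability, which includes fixation, media and biological variation.

## Cohorts and association models

The cohort generator draws covariates from the included-eye marginals of
the modelled study population (age 60.7 ± 13.2 y, HbA1c 7.48 ± 1.33%,
axial length 23.88 ± 1.34 mm, DR severity 170/101/90/36 over 397, DME
14.4%, …), at subject or eye level as appropriate; each subject
contributes both eyes with probability 0.59 (397 eyes / 250 subjects).
Outcomes are linear in the *standardized* covariates plus a subject-level
random effect carrying a fraction ρ (default 0.4) of the residual variance
— so fellow eyes are exchangeably correlated and the injected coefficients
are exactly the estimand of the downstream GEE. Default magnitudes follow
the multivariable coefficients reported for this population (e.g. severe
DR vs none on FD: −0.891); default residual SDs (0.8 / 1.0 / 0.9 for
FAZ / VD / FD) make those magnitudes detectable at the study's size
without being trivial. Taking the reported coefficients at face value on
the outcome's natural scale means extreme draws can push the synthetic
`fd` column outside the physically plausible range; the generator does not
truncate, since the association machinery is scale-agnostic.

The analysis workflow standardizes continuous predictors per variant
(full vs DME-excluded, since per-SD effects are relative to the analysed
rows), screens each factor univariately (p < 0.05 two-sided — the
modelled protocol says only "significant"; the threshold is configurable),
and fits the multivariable GEE on the selected factors: identity link,
Gaussian family, subjects as clusters, exchangeable working correlation
(two fellow eyes per subject make any richer structure unidentifiable),
robust sandwich SEs, Wald CIs. DR severity enters as three dummies versus
no DR and is screened as a block; dummies for levels absent from the
analysed rows are dropped rather than failing. Missing covariates are
handled complete-case per model. Simulation shows ~94–95% null coverage
of the 95% CIs at 200 clusters (the mild shortfall is the known
small-sample bias of the sandwich estimator) and recovery of all injected
effects within 2 robust SE at 400 subjects.

## Problem sizes and numerical conventions

Default verification sizes — 50 images for ground-truth recovery, 30 + 30
per detector for operating characteristics, 200 eyes for ICC recovery,
400 subjects for effect recovery, 500 replicates for interval coverage —
were chosen so each estimate's Monte-Carlo error is several times smaller
than the tolerance it is checked against. Component labelling uses
8-connectivity throughout; the annulus uses pixel-centre radii with a
strict inner and inclusive outer boundary; the centration and quality-score
rules are strict inequalities at their stated cutoffs; all generators are
pure functions of (parameters, seed).

## Known limitations

- The synthetic texture is geometric, not biophysical; absolute FD values
  on synthetic images (~1.88) run higher than typical clinical deep-plexus
  values because the mesh is denser and noise-free after binarization.
- QC thresholds are calibrated on this generator's fixtures; on real
  images they would need recalibration against reader labels.
- Reported clinical coefficients, ICCs and group means from the modelled
  study cannot be reproduced here (patient data not deposited); the
  package validates machinery, arithmetic consistency of the published
  counts, and statistical calibration instead.
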