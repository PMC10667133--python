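# Methods

## The quantification protocol

The pipeline quantifies intraretinal hyperreflective foci (IHRF) by
fractional depth rather than by anatomical layer. Given a reflectivity
volume and per-A-scan ILM/RPE surfaces, the retina at each A-scan is
parameterized by fractional depth f = (z − ilm)/(rpe − ilm) ∈ [0, 1] and
cut into five slabs of 20% thickness each, numbered 1 (outermost,
f ∈ [0.8, 1.0]) to 5 (innermost, f ∈ [0.0, 0.2)). Both boundaries of every
slab follow the retinal contours by construction. This avoids per-layer
segmentation (fragile over drusen) at the cost of slabs that only roughly
track named layers — a deliberate property of the protocol, not of this
implementation.

Each slab is projected to an en-face image. The projection operator is not
dictated by the protocol's source instrumentation; we use
**maximum-intensity projection** because the whole point of the downstream
threshold is to preserve the brightest lesion voxels (mean projection is
available via `projection="mean"` for sensitivity analyses). Voxels are
assigned to slabs by their center coordinate over continuous (unrounded)
interval boundaries, half-open [lo, hi) except slab 1, which is closed at
the RPE end so the outermost retinal voxel is never orphaned. Interior
voxels therefore belong to exactly one slab, while a *lesion* — a 3-D
object — can intersect two slabs and then appears in both en-face images
and is counted once in each. This double-count convention is deliberate
and is asserted by tests (one boundary lesion → total count 2).

Detection applies one threshold to all five slabs:
`threshold = 0.9 × median RPE-band reflectivity`, sampled 2 voxels below
the RPE surface at every A-scan. Anchoring to the RPE median implements
the defining property of IHRF (reflectivity ≥ RPE band); the 0.9 factor
gives speckled lesion voxels headroom, and the median is robust to locally
failed samples (vessel shadows, segmentation misses). Absolute and
percentile threshold modes are available. After binarization, connected
components (8-connectivity, the ImageJ particle-analysis default;
4-connectivity available) with area ≥ 3 px are counted as lesions. The
3-pixel floor is the standard clinical minimum size; we apply it to
en-face component area since quantification happens on en-face slabs.

### Artifact masking

The protocol's manual artifact-removal step is replaced by an automated
surrogate plus optional user-supplied ROI masks, trading fidelity to the
manual workflow for reproducibility:

* **Vessels** (applied to slabs 4–5 only): a retinal vessel is bright in
  the innermost band and shadows everything beneath it. Pixels
  suprathreshold in slab 4 or 5 whose RPE sample falls below 0.5 × the
  field-wide RPE median are flagged; flagged components of ≥ 3 px are
  dilated by one pixel and masked. The component-size floor stops isolated
  speckle coincidences from nibbling at true inner-retinal lesions.
* **RPE bleed-through** (slab 1 only): when segmentation misses a drusen
  apex, the bright RPE band itself enters slab 1 as a broad suprathreshold
  region. We mask RPE-bright slab-1 components of ≥ 40 px. A fixed guard
  band above the reported RPE surface would miss this artifact — the stray
  RPE sits up to the full drusen height above the reported surface — so
  the detector keys on component area instead: genuine IHRF at default
  radii occupy ≤ ~21 en-face pixels, an order of magnitude below drusen
  bleed regions. Limitation: a genuinely enormous lesion (> 40 px, ~0.3 mm
  across at 47 µm/px) over a missegmented drusen would be masked; such
  lesions are outside the size regime the protocol targets.

## The phantom generator

The generator emulates the features of a macular cube that this pipeline
is sensitive to, at a default 128×32×256 grid (a scaled-down analog of a
512×128 cube over 6×6 mm; full size is configurable but slower):

* five intra-retinal bands at linear-scale reflectivities
  (0.34, 0.20, 0.10, 0.14, 0.30, inner → outer) under an RPE band at 0.80.
  No quantitative band reflectivities are dictated by the protocol; these
  are conventional values chosen once so that the RPE/background contrast
  is ≥ 2.4:1 on a linear scale — the regime in which an RPE-anchored
  threshold is meaningful at all (a phantom whose background exceeds the
  IHRF threshold would not emulate any usable scan);
* smooth ILM/RPE surfaces with constant thickness (0.5 × depth), gentle
  curvature, and drusen as cosine bumps that elevate the RPE locally
  (overlaps combine as pointwise maxima);
* foci as balls of configurable center, fractional depth, radius and
  intensity ∈ [rpe_reflectivity, 1]; voxel rasterization accounts for the
  voxel's unit depth extent so a radius-1 focus always has an en-face
  footprint of ≥ 3 px. Ground truth records the slab(s) the rendered
  voxels actually occupy, using the same interval conventions as the
  geometry module, so boundary-straddling lesions are truthed in both
  slabs;
* vessels as RPE-bright spots at 8% depth with a ×0.35-dimmed shadow
  column beneath;
* speckle as multiplicative Gamma(shape, 1/shape) noise (unit mean,
  variance 1/shape), applied last; shape 20 is the default study
  condition and shape 0 disables noise. This is a standard single-lobe
  surrogate; it does not model fully developed speckle (shape ≈ 1),
  spatial speckle correlation, attenuation, or the axial PSF.

What passing phantom tests shows: the geometry, thresholding, masking and
counting machinery is correct against known truth under realistic contrast
and moderate speckle. What it does not show: performance on real scans
with pathology-dependent reflectivity, motion artifacts, or segmentation
error beyond the drusen-miss scenario modeled explicitly.

## The cohort simulator

Per-slab baseline counts are Poisson with means (1.12, 2.54, 0.94, 0.08, 0)
per eye — per-slab totals of a published 52-eye analyzed subgroup divided
by 52 — and follow-up counts add an independent Poisson increment to match
the follow-up means (3.73, 5.52, 1.92, 0.44, 0); counts therefore never
decrease, mirroring the observed monotone 2-year increase (a decrement
option was considered and left out: the reference data show none).
Slab 5 means are pinned to zero by validation because the reference cohort
observed no innermost-slab lesions at either visit — this is a property of
the simulated *data*, never of the detector, which the tests prove will
happily count implanted slab-5 lesions. Progression is Bernoulli with
log-odds = logit(0.15) + Σ βk·nk; default β are the log adjusted odds
ratios (1.74, 1.38, 1.13, —, —) of the reference cohort. Under these
defaults the marginal progression fraction is ≈ 45%, matching the analyzed
IHRF-carrying subgroup (23/52 = 44%), not the screened cohort's 19%.
Eyes are independent `SeedSequence` substreams of one master seed, so
prefixes of a larger cohort reproduce a smaller one exactly.

## Statistical stage

* Paired *t* on per-eye per-slab counts; differences are follow-up −
  baseline, so positive *t* means counts increased. Zero-variance
  differences: identical visits give t = 0, p = 1; a constant nonzero
  shift is flagged `degenerate` with no p-value.
* Logistic models are ML fits (statsmodels) with Wald CIs and p-values,
  the convention of the SPSS-era clinical literature this protocol comes
  from. Predictors per slab: baseline count (continuous), 2-year change,
  or presence/absence with absence as reference. A predictor without
  variation, or whose fit diverges (|coef| > 12 or SE > 30, or a solver
  failure — the complete/quasi-separation signature), is reported
  `inestimable`/NA rather than with a meaningless estimate.
  Profile-likelihood CIs (`ci_method="profile"`) and Firth-penalized
  estimation (`penalized=True`) are available for the univariate model.
* The multivariate predictor set defaults to the slabs whose predictor
  varies in the data (slabs 1–3 for cohorts shaped like the reference
  study); an explicit set can be passed.
* Two eyes of one patient are treated as independent (eye-level models,
  as in the reference analysis); the cohort table carries `patient_id`
  so users can subsample one eye per patient for sensitivity checks.
* Inter-grader agreement is unweighted Cohen's κ with the large-sample
  SE √(p̂o(1−p̂o)/(n(1−p̂e)²)) for the CI and the Fleiss–Cohen–Everitt
  null SE for the p-value. The repeatability statistic in this literature
  is sometimes labeled ICC; κ is what a 2×2 presence/absence grading
  comparison supports, so κ is what we implement.
* Report rounding is half-up: 1 decimal for means and percentages, 2 for
  odds ratios — the printed precision of clinical tables. Note that
  published per-eye means are not always recoverable from published
  totals (totals/52 here yields 4.7 at baseline where 4.6 was printed);
  the report computes, it does not transcribe.

## Numerical and design choices

* Slab-boundary arithmetic multiplies by 5 rather than dividing by 0.2
  (exact in binary floats at the printed boundaries), and boundary
  fractions own the outer slab: f = 0.8 belongs to slab 1.
* Empty slab intervals (retina thinner than ~5 voxels) fall back to the
  nearest voxel with a logged warning instead of failing the whole eye.
* Connected components use `scipy.ndimage.label`; a deliberately naive
  BFS flood fill in `ihrf.benchmark` is the independent oracle, and the
  two are compared exactly on random masks in the test suite.
* Determinism: every stochastic stage takes a seed or Generator; the
  pipeline writes a provenance sidecar (seed, config hash, version) next
  to each artifact and re-running a config reproduces byte-identical CSVs.
* Problem sizes in the test suite and acceptance script (100-phantom
  recovery runs at the default 128×32×256 grid, 5000-eye odds-ratio
  recovery, 500-cohort CI calibration at n = 300) were chosen to hold
  Monte-Carlo error comfortably below the assertion bands while keeping a
  full run in the tens of seconds on one CPU.

## Package shape

The imaging stages are a functional pipeline (specs in, tables out) —
there is no fitted model there to hang a Model/Results API on. The
statistical stage, which *is* a model fitted to data, follows the
statsmodels idiom: `ProgressionModel(cohort).fit()` returns a
`ProgressionResults` with `summary()`, the four report tables, and
plotting. `build_report` renders results to CSV + markdown, and the
`ihrf` CLI (simulate/slabs/detect/analyze/report/all/fixtures) wraps the
whole chain for shell use.

## Known limitations

* The phantom's speckle is spatially white; real OCT speckle is
  correlated at the PSF scale, so the false-positive rates measured here
  are optimistic for real data.
* The artifact mask handles the two modeled confounders (vessels, drusen
  bleed with missed segmentation); hyperreflective artifacts with other
  geometries still require the user-mask pathway.
* The vessel detector can also fire over deeply shadowed drusen regions,
  masking inner-slab pixels there; this costs sensitivity only for inner
  lesions directly over large missegmented drusen.
* Logistic defaults assume eye-level independence and apply no
  multiple-testing correction, matching the reference analysis
  conventions rather than best current practice.
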