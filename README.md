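# ihrf — depth-stratified quantification of intraretinal hyperreflective foci

Intraretinal hyperreflective foci (IHRF) are discrete, well-circumscribed
bright lesions inside the neurosensory retina on OCT, with reflectivity at
least that of the retinal pigment epithelium (RPE) band. They are among the
strongest OCT biomarkers of progression from intermediate age-related
macular degeneration (iAMD) to late AMD, and *where* they sit in the retina
matters: lesions in the outer retina, nearest the RPE, carry the greatest
progression risk.

This package implements the depth-stratified quantification protocol and
its longitudinal statistics as a tested, reusable pipeline:

1. **Slab geometry** — the retina between the internal limiting membrane
   (ILM, fractional depth 0) and the inner RPE surface (fractional depth 1)
   is split into 5 sequential slabs of equal fractional thickness, numbered
   from the outside in (slab 1 = 80–100%, adjacent to the RPE; slab 5 =
   0–20%, under the ILM). Both slab boundaries follow the segmented
   contours. Each slab is projected to an en-face image (maximum-intensity
   by default).
2. **Detection** — a single reflectivity threshold, anchored to the median
   RPE-band reflectivity (IHRF are by definition at least RPE-bright), is
   applied to every slab; images are binarized, confounders (vessel
   shadows, RPE bleed-through over drusen) are masked, and connected
   components of ≥ 3 pixels are counted as lesions, ImageJ
   particle-analysis style. A lesion straddling a slab boundary appears in
   both adjacent en-face images and is counted once in each.
3. **Progression statistics** — paired *t* tests of per-slab counts between
   visits, univariate and multivariate logistic regressions of progression
   on per-slab counts (continuous), 2-year changes, and presence
   (categorical), reported as odds ratios with Wald 95% CIs
   (`ProgressionModel(...).fit().summary()`), plus unweighted Cohen's κ for
   inter-grader agreement.
4. **Synthetic OCT phantoms** — since clinical volumes cannot be bundled,
   a phantom generator renders scaled-down macular cubes (128×32×256 by
   default) with layered reflectivity, drusen-elevated RPE, implanted foci
   of known fractional depth, vessel/shadow confounders and multiplicative
   Gamma speckle, together with a ground-truth table; a cohort simulator
   draws two-visit per-slab counts and progression labels from a known
   logistic model so the statistical stage can be validated end to end.

## Worked example

```python
from ihrf import (VolumeSpec, FocusSpec, generate_surfaces,
                  render_volume, quantify_eye)

spec = VolumeSpec(speckle_shape=20.0, seed=0)
surfaces = generate_surfaces(spec)
foci = [
    FocusSpec(x=30, y=8,  frac_depth=0.90),  # outer retina, slab 1
    FocusSpec(x=64, y=16, frac_depth=0.68),  # slab 2
    FocusSpec(x=98, y=24, frac_depth=0.50),  # mid retina, slab 3
]
volume, truth = render_volume(spec, surfaces, foci)
table = quantify_eye(volume, surfaces)
print("truth    :", truth.per_slab_counts())
print("detected :", table.per_slab_counts())
print("threshold:", round(table.threshold, 3))
```

prints

```
truth    : [1 1 1 0 0]
detected : [1 1 1 0 0]
threshold: 0.705
```

i.e. under shape-20 speckle the three implanted lesions are recovered in
their true slabs (counts are ordered slab 1 → 5, outer → inner) with a
threshold of 0.9 × the median RPE reflectivity. The statistical stage runs
the same way on a simulated cohort:

```python
from ihrf import CohortSpec, simulate_cohort, ProgressionModel

cohort = simulate_cohort(CohortSpec(n_eyes=300, seed=1))
print(ProgressionModel(cohort).fit().summary())
```

whose output begins

```
IHRF progression analysis
============================================================
Eyes analyzed: 300; progressed to late AMD: 138 (46.0%)
Total IHRF: 1313 at baseline, 3419 at follow-up (mean per eye 4.4 -> 11.4)

Per-slab lesion counts (paired t, follow-up - baseline)
 slab  baseline_total  baseline_mean  baseline_sd  followup_total  followup_mean  followup_sd p_value
    1             338            1.1         1.12            1108            3.7         1.93  <0.001
    2             709            2.4         1.50            1619            5.4         2.38  <0.001
...
```

followed by the three odds-ratio tables (baseline counts, 2-year change,
presence/absence), with inestimable cells — e.g. slab 5, which has no
lesions — reported as `NA`.

The same pipeline is scriptable from the shell:

```bash
ihrf all --demo --outdir demo_out --seed 7   # simulate → slabs → detect → analyze → report
ihrf fixtures --outdir fixtures              # bundled demonstration phantoms
```

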