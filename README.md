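# ridgemetry

Quantification of **fibrovascular ridge thickness** in retinopathy of
prematurity (ROP) from volumetric swept-source OCT, with a synthetic phantom
generator and the clustered statistics used to relate the measurement to
clinical disease stage.

In ROP, disease *stage* describes the pathology at the junction between
vascularized and avascular retina: a demarcation line (stage 1), an elevated
ridge (stage 2), or extraretinal fibrovascular proliferation (stage 3).
Ultra-widefield OCT resolves this junction in depth, so the axial height of
the ridge becomes a quantitative, continuous biomarker of stage severity.
This package is for imaging researchers who want a tested, reproducible
implementation of that measurement pipeline and its statistical analysis —
and, because infant OCT scans are not publicly shareable, a synthetic data
module that emulates the whole study design with known ground truth.

## The measurement

For one exam the pipeline is:

1. **En face projection** of the volume (mean or maximum intensity along
   depth) to visualize the ridge, with optional adjacent-B-scan averaging.
2. **Ridgeline trace**: an open polyline on the en face image following the
   ridge crest along the vascular–avascular junction.
3. **Curved strip extraction**: the trace is resampled to uniform arc-length
   spacing and the A-scan at each sample is interpolated bilinearly,
   yielding a curved B-scan that follows the ridge.
4. **Two-surface segmentation** on the strip: the inner ridge surface
   (tissue–vitreous interface) and the retinal pigment epithelium (RPE).
5. **Thickness**: per column `j`,
   `t_j = (rpe_row_j − inner_row_j) × Δz`, with `Δz` the axial pixel size in
   μm (4.4 μm for the emulated device: a 6 mm range in air is 4.5 mm in
   tissue at group index 1.333, over 1024 samples). The exam summary is the
   **top-10 maximum thickness**: the mean (with SD) of the 10 largest `t_j`
   along the traced ridge.

Cohort-level analyses: intergrader agreement (percent exact agreement,
weighted Cohen's κ on ordinal 0–3 labels, Pearson r on continuous 0.1-step
labels), per-stage mean thickness from a **generalized estimating equation**
(identity link, exchangeable working correlation within patient, robust
SEs), **Spearman ρ** between continuous stage and thickness, test–retest
repeatability (one-way random-effects **ICC** and mean per-eye **CoV**), and
a pre/at/post-treatment windowed comparison for eyes treated with
intravitreal anti-VEGF.

## Worked example

Measure a noise-free phantom with a 200 μm retina and a 300 μm ridge:

```python
import numpy as np
from ridgemetry import PhantomParams, generate_phantom_volume, measure_exam

params = PhantomParams(
    n_axial=256, n_fast=96, n_slow=96,
    baseline_retina_um=200.0, ridge_height_um=300.0, speckle_snr=np.inf,
)
volume, truth = generate_phantom_volume(params, seed=1)
result = measure_exam(volume, truth.true_ridgeline)
print(f"analytic max thickness: {params.true_max_thickness_um:.1f} um")
print(f"measured (top-10 mean): {result.mean_um:.1f} um "
      f"(SD {result.sd_um:.1f}, n_used {result.n_used})")
```

prints

```
analytic max thickness: 500.0 um
measured (top-10 mean): 499.7 um (SD 0.0, n_used 10)
```

i.e. the automated pipeline lands within one axial pixel (4.4 μm) of the
analytic truth. A full simulated study — 25 patients, 50 eyes, ~125 exams
with two noisy graders, 20-eye repeat captures, and 4 treated infants —
runs from one seed:

```bash
ridgemetry run --out study/ --seed 1
cat study/report.txt
```

```
ridgemetry 0.1.0 study report (seed 1)
config sha256: 17e22206529854c1245c0644c13ebc624447296c194ac62952a6bb4ed69709c7

cohort: 25 patients, 50 eyes, 125 exams (1 excluded, mean stage < 0.5)
agreement: 91.1% exact, weighted kappa 0.89, Pearson r 0.95
stage 1: 266.2 (17.2) um [GEE, robust SE, n=56]
stage 2: 335.1 (14.2) um [GEE, robust SE, n=46]
stage 3: 477.0 (31.6) um [GEE, robust SE, n=22]
Spearman rho (continuous stage vs thickness): 0.635
repeatability: ICC 0.96, mean CoV 6.2% (20 eyes, 40 measurements)
treatment windows (um): pre 342.9 (15.2), at 400.7 (12.5), post 307.6 (15.4)
```

The per-stage GEE means recover the generator's calibration (264.2 / 334.2 /
495.0 μm for stages 1/2/3) to within their robust SEs; thickness rises to
the treatment visit and falls after it. Exams with a mean continuous stage
label below 0.5 carry no perceptible ridge and are excluded before analysis.

Other entry points: `ridgemetry simulate | project | strip | measure |
analyze` operate on TIFF volumes with JSON sidecars, `slow,fast` trace CSVs,
and the documented cohort CSV schema; see `--help` on each.

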