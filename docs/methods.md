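# Methods

This note documents the models, numerical choices, and assumptions behind
`ridgemetry`: what the synthetic data emulate, how the measurement pipeline
works, and which decisions were genuinely open.

## Coordinate and unit conventions

OCT volumes are arrays indexed `(slow, axial, fast)`: *slow* selects a
B-scan, *axial* runs down an A-scan with **row 0 on the vitreous side** (the
top of a displayed B-scan), *fast* indexes A-scans within a B-scan. En face
points are `(slow, fast)` pixel coordinates, 0-based, real-valued, y-down.
All thicknesses are micrometres; the axial pixel size defaults to 4.4 μm —
a 6 mm imaging range in air divided by a group refractive index of 1.333
gives 4.5 mm in tissue, and 4.5 mm / 1024 samples ≈ 4.4 μm/px. The group
index default (1.333) is the conventional value for retinal tissue; the
1024-sample depth is chosen so the per-pixel scale comes out at 4.4 μm.

## Phantom model

A phantom is a smooth retina with a localized fibrovascular ridge:

* The **RPE** is a flat plane at `rpe_depth_frac` (default 0.75) of the
  axial range. The **inner surface** lies `baseline_retina_um` (default
  200 μm) above it.
* The **ridge** elevates the inner surface by a Gaussian bump: on a circular
  arc (center angle and extent in clock hours, radius in en face pixels,
  default 0.35 of the lateral field) the elevation is `ridge_height_um`;
  it decays as `exp(−d²/2σ²)` with en face distance `d` from the arc
  (σ = `ridge_profile_sigma_um`, default 300 μm). A single transverse width
  parameter suffices because the bump is a surface elevation — it has no
  independent axial extent.
* **Rendering**: vitreous at `background_level` (10), retina at
  `tissue_level` (100), a 3-row bright band centred on the RPE row peaking
  at `rpe_level` (255), background again below. Surfaces are quantized to
  integer rows for rendering; the stored truth is the *rendered* rows, so
  noise-free segmentation can recover them exactly, and the brute-force
  maximum of `(rpe − inner) × Δz` sits within one axial pixel of the
  analytic `baseline + ridge_height`.
* **Speckle** is multiplicative unit-mean gamma noise with SD
  `1/speckle_snr` (shape `snr²`). At SNR 1 this is exactly the exponential
  intensity statistics of fully developed speckle; larger SNR emulates the
  effective averaging of real acquisitions. Default SNR 3 (≈33% intensity
  fluctuation) is typical of displayed, lightly averaged linear-scale OCT.

Not modelled: scanning-geometry distortion, lens-module field curvature,
motion artifacts, vessel shadows, and B-scan misregistration. Averaging of
adjacent B-scans is therefore implemented without registration.

## Measurement pipeline

**Strip extraction.** The traced ridgeline is resampled to uniform
arc-length spacing (default 1 px, preserving native lateral sampling);
samples sit at arc lengths `0, s, 2s, …`, giving `floor(L/s)+1` columns,
with the far endpoint included when `L` is a multiple of `s`. Each column
is the A-scan at the sample position, interpolated **bilinearly** between
the four neighbouring lateral columns — sub-pixel manual traces are the
norm, and nearest-neighbour sampling would alias thickness at crest
crossings.

**Segmentation.** Automated two-surface segmentation runs per strip column
after 2-D Gaussian smoothing (axial σ 1.5 px, lateral σ 1 px):

* *Structure check*: the column's smoothed peak must exceed
  `min_peak_contrast` (default 3×) times its dark floor (25th percentile —
  vitreous plus sub-RPE background). Columns failing it (noise or
  background only) are flagged invalid, never guessed. A strip with no
  dynamic range at all (constant) raises, since range-relative thresholds
  are meaningless there.
* *Inner surface*: first axial index (from the vitreous side) where the
  smoothed intensity stays above `min + 0.25 × range` for ≥ 3 consecutive
  pixels. The threshold fraction must stay below the tissue contrast
  (≈ 0.37 of the phantom dynamic range) with margin for speckle.
* *RPE*: brightest smoothed pixel at or below the inner surface, refined to
  sub-pixel by a parabola through its two neighbours (offset clamped to
  ±0.5 px).

With smoothing enabled, boundary positions shift by a fraction of a pixel,
so recovery is validated at 1-pixel tolerance; with smoothing disabled on
noise-free data the recovery is exact. Manually delineated surfaces can be
substituted via a `column_index,inner_row,rpe_row` CSV.

**Summary statistic.** Thickness is `(rpe − inner) × Δz` per valid column;
the exam summary averages the **10 largest** values ("top 10"), reporting
their population SD and the count actually used. The 10 values are the 10
largest per-column values with no spatial-separation constraint — the
natural pixelwise reading; if fewer than 10 valid columns exist, all are
averaged (fail-soft with `n_used` recording the shortfall).

## Cohort and label model

Patients contribute two eyes; eyes contribute 1–4 sessions (probabilities
0.10/0.40/0.34/0.16, mean ≈ 2.56, matching 128 volumes over 50 eyes). Each
eye draws an ordinal stage from the mix 50/128, 65/128, 13/128 (stages
1/2/3) and a continuous severity `k + δ`, δ ~ N(0, 0.2) truncated to ±0.45
so it rounds back to `k`. Latent eye thickness is

```
stage_mean[k] + 115.4·δ + N(0, stage_sd[k]) + N(0, σ_patient) + N(0, σ_eye)
```

with stage means 264.2/334.2/495.0 μm (the calibration targets),
`stage_sd` = 40/45/65 μm, σ_patient = 40 μm (shared by both eyes — the
source of intereye correlation), σ_eye = 20 μm (shared by the eye's
sessions). The severity slope 115.4 μm per stage unit is the secant slope
of the calibrated stage means, `(495.0 − 264.2)/2`, making thickness vary
continuously with severity *within* an ordinal category; because δ is
symmetric with zero mean, the conditional mean per ordinal stage remains
exactly `stage_mean[k]`, which the GEE parameter-recovery tests rely on.
Each session adds N(0, 27 μm) capture noise — chosen so the expected
per-eye CoV of paired captures, `E[SD]/mean ≈ 0.8·27/330`, is ≈ 7%.

**Grader model.** Each of two graders observes the continuous severity plus
independent N(0, `grader_noise_sd`) error, quantized to 0.1 steps and
clipped to [0, 3]; ordinals are the continuous labels rounded half-up. The
default SD 0.18 is set analytically: with severity dispersed ±0.2 around an
integer stage, each grader crosses an ordinal boundary with probability
≈ 6%, giving ≈ 88% expected exact agreement. **This generative grader model
is an assumption** — no generative description of grader behaviour exists —
and it is deliberately simple: a single symmetric noise parameter cannot
simultaneously reproduce a high exact-agreement rate and a low chance-
corrected κ (real graders differ by calibrated bias and marginal imbalance,
which depress κ at fixed agreement). Simulated κ and Pearson r therefore
run higher than is typical of real grader pairs; conclusions about grader
behaviour should not be read off the synthetic cohort.

**Adjudication and exclusion.** The graders' continuous labels are
averaged; if their ordinals disagree, the average rounded to the nearest
integer is the adjudicated stage, with **.5 rounding up** (the protocol
never exhibits a .5 case; the tie-break is fixed here once and used
everywhere). Exams with mean continuous label **< 0.5** are excluded
(strictly less than: 0.5 itself is retained).

**Treatment trajectories.** Thickness is piecewise linear around the
treatment visit: rising at 35 μm/wk before week 0 and falling at 60 μm/wk
after, plus N(0, 15 μm) per visit. The slopes are set from the emulated
pre/at/post window means (342.4 → 394.4 → 304.0 μm over ±1–2 weeks); the
observation schedule is weekly from −2 to +2.

## Statistical analyses

* **GEE stage means**: `thickness ~ C(stage) − 1` (no intercept, so the
  coefficients are the per-stage marginal means), Gaussian family, identity
  link, **exchangeable** working correlation with **patient** as the
  cluster, robust sandwich SEs. A single-level patient cluster subsumes
  both intereye and interexamination correlation at the cost of assuming
  them equal; the exact clustering specification is an assumption. With one
  record per cluster the fit reduces to per-stage sample means (tested to
  1e-8). P-values test each stage mean against zero, two-sided.
* **Weighted κ**: Cohen's κ with **linear** weights by default (quadratic
  behind a flag); the weight matrix is built on the jointly observed
  category range. Computed via statsmodels, validated against a
  hand-computed contingency-table oracle.
* **Spearman ρ** with average-rank ties (scipy).
* **ICC**: one-way random-effects, single-measurement form ICC(1,1) from
  the ANOVA decomposition, with the standard unbalanced-design correction
  `n0`; implemented directly (the closed form also handles unequal repeat
  counts) and cross-checked against pingouin's ICC(1,1) on balanced data.
  Identical repeats give ICC = 1 and CoV = 0 exactly. The **CoV** is
  computed per eye (sample SD of its repeats over its mean, ×100) and then
  averaged across eyes.
* **Treatment windows**: pre = [−2, −1], at = (−1, +1), post = [+1, +2]
  weeks from treatment (closed outer boundaries; records outside every
  window are excluded with a count). Right and left eyes of an infant are
  averaged per visit before summarizing; each window's mean and robust SE
  come from an intercept-only GEE clustered by patient, degrading to a
  simple mean (with a warning) for a single infant or zero residual
  variance. Window SEs are robust model SEs; the per-stage uncertainties
  are likewise reported as SEs throughout (the SD/SE labelling of such
  model outputs is inconsistent in common usage, so the report text says
  "robust SE" explicitly).
* All tests two-sided, α = 0.05, no multiplicity correction.

## Determinism and problem sizes

All randomness descends from one integer seed through a
`numpy.random.SeedSequence` hierarchy; identical configs produce
byte-identical cohort CSVs and results JSON. The test suite runs phantoms
at compact sizes (64–96 lateral, 192–256 axial pixels — the geometry is
scale-free, and the device axial scale is kept at 4.4 μm/px), 100
GEE-recovery replicates of 100-patient cohorts, and a 3×3 variance grid
with 400 eyes per cell for the ICC closed form; the full suite completes in
well under a minute.

## Known limitations

* Segmentation is tuned for phantom-like contrast (bright RPE band, darker
  tissue, dark vitreous); real scans with shadowing, detachment, or
  retinoschisis would need the manual-surface input path.
* No B-scan registration before averaging; no dewarping of wide-field
  contact-lens geometry.
* The en face projection is full-depth; depth-windowed projections are not
  implemented.
* The grader noise model is symmetric and bias-free (see above).
* Ridgeline detection is not automated: measurement requires a trace
  (manual for real data, ground-truth for phantoms).
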