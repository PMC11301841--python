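# Methods

This note records, in the package's own words, the measurement model behind
`choroquant`, the parameter choices with their units and rationale, what the
synthetic generators do and do not emulate, and the numerical and design
decisions a user should know before trusting the outputs.

## 1. Measurement model

### 1.1 Inputs

A fovea-centred OCT B-scan is a 2-D array of reflectance values with known
sampling: `axial_um_per_px` (depth, µm per pixel) and `lateral_um_per_px`
(transverse, µm per pixel at the nominal eye geometry). The choroid is
delimited per column by two boundaries: `upper_px` (the Bruch's-membrane
line) and `lower_px` (the choroid–sclera interface). The band is inclusive:
a column with `upper = lower` is one pixel thick. Boundaries may come from a
label image, from a CSV produced by an external segmenter, or from the
bundled baseline gradient segmenter (`baseline_segment`), which exists to
make the CLI runnable end-to-end, not to compete with clinical-grade
segmentation.

### 1.2 Binarization (Niblack)

Within the band, pixel `p` is labelled **lumen** when its value is below the
auto-local Niblack threshold

```
T(p) = mean_w(p) + k * sd_w(p)
```

where `mean_w` and `sd_w` are the mean and *population* standard deviation
over a square window of side `window_px` centred on `p`, computed over the
whole image with reflective padding at the borders. Defaults:
`window_px = 51`, `k = -0.2`. The window must be large relative to a lumen
cross-section so the local statistics are dominated by stroma; negative `k`
pushes the threshold below the local mean, which suppresses false lumen
calls in homogeneous stroma. An optional median prefilter
(`median_prefilter_px`, default 0 = off) is available for noisier inputs.

Note the sign convention: some libraries define Niblack as
`mean - k * sd`; here the formula is `mean + k * sd` with `k = -0.2`, which
is the same threshold. The implementation is checked pixel-for-pixel
against an independent double-loop oracle in the tests.

Derived quantities per analysed section:

- **LA** — luminal area (mm²), **SA** — stromal area (mm²),
  **TCA = LA + SA**, **CVI = LA / TCA** (dimensionless).
- **ChT** — mean choroidal thickness (µm), computed from the per-column
  band height `(lower - upper + 1) * axial_um_per_px`.

### 1.3 Lateral magnification correction (Bennett)

OCT scan length is nominally calibrated for an emmetropic eye; in long
(myopic) eyes the same scan angle covers more retina. The corrected
transverse length is

```
t = (AL - 1.82) / 22.58 * s
```

with `AL` the axial length in mm and `s` the nominal length. The factor is
exactly 1 at `AL = 24.4` mm (in IEEE double arithmetic,
`(24.4 - 1.82) / 22.58 == 1.0`). Only lateral distances are corrected;
axial sampling is independent of eye geometry, so ChT is never rescaled.
Areas scale linearly with the factor; CVI, being a ratio of areas over the
same pixels, is invariant. AL must lie in the physiological guard band
[15, 40] mm; values outside raise an error rather than silently
extrapolating.

### 1.4 Regional grid

Each meridian's 6-mm section is split at −3, −1.5, −0.5, +0.5, +1.5, +3 mm
from the fovea, *measured in corrected millimetres*, giving five regions:
two perifoveal 1.5-mm flanks, two parafoveal 1-mm rings and the central
1-mm "C". Vertically the names are S2, S1, C, I1, I2 (negative offsets are
superior); horizontally T2, T1, C, N1, N2 for right eyes and the mirror
image for left eyes, so "N" is always nasal. Image columns are assigned to
regions by their corrected distance from the fovea column; the fraction of
each region's span falling outside the image is reported as
`clamped_fraction`, and a region with most of its span missing yields NaN
rather than a silently truncated value. Perifoveal LA/SA are additionally
reported divided by 1.5 (`LA_norm_mm2`, `SA_norm_mm2`) so that all five
regions are comparable per millimetre of section; whole-meridian LA/SA are
totals over the analysed section.

## 2. Synthetic data

### 2.1 B-scan generator (`simulate_bscan`)

What it emulates: a fovea-centred swept-source B-scan of the choroid with
(i) smooth sinusoidal upper/lower boundaries (2–4 waves, relative waviness
0.15), (ii) elliptical vessel lumens with lateral semi-axes 6–14 px and
axial semi-axes 3–8 px, (iii) three reflectance levels (stroma 200, lumen
50, background 20, arbitrary units) under multiplicative gamma speckle
(shape 70, ≈12 % coefficient of variation, contrast-to-noise ≈ 6 between
stroma and lumen). Defaults: 400 × 512 px at 3.9 µm axial and 11.72 µm
lateral sampling (≈6 mm width at the nominal geometry), 300 µm mean
thickness.

The generator returns exact truth: the boundary arrays, the boolean lumen
mask and `true_lumen_fraction` (lumen pixels / band pixels). Lumen
placement draws from a seed-determined candidate stream that does not
depend on the target fraction; the realized set is the shortest prefix
whose union reaches the target, so the achieved fraction is monotone in the
target for a fixed seed, and an unreachable target raises an error naming
the fraction achieved.

What it does **not** emulate: retinal layers above Bruch's membrane, vessel
shadowing, depth-dependent signal roll-off, motion artefacts, anisotropic
speckle, or anatomically realistic vessel branching. It is a test bed for
the quantification pipeline, not an image-realism benchmark.

### 2.2 Cohort generator (`simulate_cohort`)

Subjects (default 720) each contribute two eyes. Each subject is assigned a
fundus category — C0 (no myopic fundus changes), C1 (tessellation only),
C2 (diffuse chorioretinal atrophy) — with default proportions
(0.066, 0.760, 0.174). Category is a subject-level trait; `dca` is the C2
indicator. Continuous traits (age, height, AL, corneal curvature, and the
choroidal metrics ChT_V, LA_V, SA_V, ChT_N2, LA_N2, SA_N2) are drawn per
group from normal distributions; eye-level metrics share a subject random
effect so the intra-subject correlation is a configurable `rho` (default
0.7): `x = mu + sd * (sqrt(rho) * u_subject + sqrt(1 - rho) * v_eye)`.
Metrics are floored at 1e-3 to stay positive. Visual-field mean deviation
(MD, dB) follows a linear link on height, AL, corneal curvature and LA_V
with Gaussian noise (sd 2.0 dB), and each eye gets a reliability flag
(default P = 0.86). An optional `logistic_link` mode instead assigns C2
status from a logistic model on Z-scored covariates, which is what the
parameter-recovery tests use: the generating odds ratio is known exactly.
Boolean `excl_*` columns carry the five exclusion reasons used by
`apply_exclusions`.

Group means are patterned on published highly-myopic cohort summaries so
that the synthetic cohort lives on a clinically plausible scale; they were
fixed **before** the acceptance tests were run and are never tuned to make
a test pass. What the cohort generator does not emulate: measurement error
in AL, age-dependent choroidal thinning within group, missing data other
than VF reliability, or selection effects beyond the explicit exclusion
flags.

## 3. Statistics

- **Exclusions**: an eye is removed if any `excl_*` flag is set; the ledger
  reports removals by reason, by side, and by reason × side. Because one
  eye can carry several flags, per-reason counts can sum to more than the
  number of removed eyes.
- **Group comparisons**: Gaussian GEE with an exchangeable working
  correlation clustered on subject, adjusted for age and AL by default;
  the three pairwise category contrasts are Wald tests with Bonferroni
  adjustment `p_adj = min(1, 3 * p_raw)`. Rank-deficient designs raise a
  named error instead of returning arbitrary coefficients.
- **DCA logistic models**: GLM (binomial) with cluster-robust (subject)
  covariance; continuous covariates are Z-scored on the analysis sample so
  odds ratios are per SD. Coefficients beyond |30| on the standardized
  scale are treated as separation and raise an error.
- **MD linear models**: OLS with cluster-robust covariance; reported with
  both raw B and standardized beta (`B * sd(x) / sd(y)`), restricted to
  reliable visual fields, on all eyes or the pathologic-myopia /
  non-pathologic-myopia subsets.
- **ROC**: AUC via the rank-sum (Mann–Whitney) identity with midrank tie
  handling; the standard error is DeLong's, implemented in-house and
  cross-checked against R's pROC in the tests. Candidate cut-offs are
  midpoints between consecutive unique values; the Youden-optimal cut-off
  breaks ties toward higher sensitivity, then the smaller threshold.
  Orientation (`lower` = smaller values indicate disease) is chosen by AUC
  unless fixed by the caller. Age strata: All, 18–30, (30, 40], (40, 50],
  (50, 60]; strata with no data or one outcome class yield NaN rows rather
  than errors.

## 4. Numerical choices

- Niblack local moments use `scipy.ndimage.uniform_filter` with reflective
  boundary handling, mathematically identical to `np.pad(mode="symmetric")`
  plus a sliding window; variance is the population form
  `E[x²] − E[x]²` computed in float64.
- The Bennett fixed point is exact in floating point; the acceptance script
  still recovers it by Brent root-finding on `lateral_factor(al) − 1` from
  several brackets and checks bracket-independence, so the script verifies
  the implementation rather than restating the constant.
- AUC uses `scipy.stats.rankdata` midranks; all tie handling is therefore
  identical to the standard Mann–Whitney statistic.
- TIFF round-trips store reflectance as uint16 at a fixed scale of 64
  counts per unit, lossless for the generator's value range.
- CLI manifests contain no timestamps, so identical seeds give
  byte-identical output trees.

## 5. Design decisions

- Boundaries are an explicit input type, not a hidden pipeline stage:
  clinical users will bring their own segmentation, and the quantification
  must be testable against exact truth masks independently of any
  segmenter.
- The band convention is inclusive on both boundaries everywhere
  (thickness, masks, truth), so there is no off-by-one ambiguity between
  the generator and the measurement code.
- Magnification correction is applied at the *metric* level (suffix-driven:
  `*_axial_px → _um` uncorrected, `*_lateral_px → _um` corrected,
  `*_area_px → _mm2` corrected once), keeping pixel-space processing
  geometry-free and making the correction auditable in one place.
- Statistics are built on `statsmodels` estimators; the package adds the
  clinical conventions (clustering, Z-scoring, Bonferroni, Youden rules)
  rather than reimplementing regression. The AUC/DeLong code is in-house
  because the cut-off search needs the full candidate sweep, and it is
  cross-checked against independent implementations in the tests.

## 6. Limitations

- The baseline segmenter is a simple gradient-step finder; on low-contrast
  scans its boundaries, and everything downstream, will be poor. Use
  external boundaries for real data.
- Niblack binarization has a known false-lumen rate in homogeneous stroma
  that depends on the contrast-to-noise ratio; the defaults are tuned for
  the generator's CNR ≈ 6 regime and should be revisited for other devices.
- The Bennett correction assumes the nominal calibration geometry of the
  formula; devices with different internal assumptions need a different
  constant pair.
- The cohort generator's group parameters are plausible, not fitted; it
  supports method validation (type-I error, parameter recovery, scale
  checks), not epidemiological inference.
- Horizontal-meridian handedness (OD/OS mirroring) is taken from the
  `laterality` field of the scan; mislabelled laterality silently swaps
  nasal and temporal regions.
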