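# Methods

## Texture model

The Corticalization Index treats an ROI at the implant neck as a sample of
a stationary texture and summarizes it with two second-order statistics and
one first-order statistic.

**Quantization.** Raw grey values (8- or 12-bit) are reduced to `Ng`
discrete levels before either matrix is built. Default: `Ng = 64`,
min–max mode (patch minimum → level 0, maximum → level `Ng − 1`, uniform
bins). A mean ± 3σ clipping mode is provided for workflows that normalize
against outliers, and a fixed-range mode bins the full dynamic range of
the declared bit depth. The choice is recorded in feature output because
absolute feature values (and hence CI magnitudes) depend on it. A constant
patch quantizes to all-zero levels and is flagged *degenerate* rather than
raising: degeneracy is a property of the data, and only the CI — whose
denominator would be zero — is an error downstream.

**Co-occurrence / difference entropy.** The GLCM counts ordered pixel
pairs at offset distance `d = 5` (the clinical protocol's pair distance)
along a direction; with symmetric accumulation (default, the standard
Haralick convention) each pair is counted in both orders. The difference
distribution `p_{x−y}(i)` collects the mass at `|row − col| = i`, and
difference entropy is its Shannon entropy with `0·log 0 := 0` by
continuity. The common (base-10) logarithm is the default; natural log is
available for comparability with tools that use it. `DifEntr` lies in
`[0, log10 Ng]`, attaining the bound iff `p_{x−y}` is uniform.

**Run lengths / long-run emphasis.** The GLRLM counts maximal runs of
equal quantized level along a scan direction; every pixel belongs to
exactly one run per direction, which the implementation checks as an
invariant (`Σ k·p(i,k)` = pixel count). `LngREmph ≥ 1`, with equality iff
every run has length 1.

**Directions.** Only the pair distance is fixed by the protocol; the
direction set is not. Default: the horizontal (0°) offset for both
matrices, with optional 4-direction computation. Multi-direction values
are aggregated as the arithmetic mean of per-direction feature values
(`average-features`); matrix-level averaging and per-direction reporting
are alternatives, and per-direction values are always retained.

**Mean optical density** is computed on the *raw* grey values, never the
quantized levels — otherwise MOD (and CI) would depend on `Ng`, which the
index definition does not suggest.

**Comparability caveat.** Published cohort CI magnitudes depend on the
originating software's unstated settings (grey-level depth, direction
handling, normalization). This package pins its own conventions and prints
them with every output; matching another tool's absolute values requires
matching its settings. The risk-scale thresholds are therefore
configuration (defaults 300/500/1200), not constants.

## Risk scale

The published scale labels CI < 300 low, "around or above 500" medium and
\> 1200 high/critical, leaving [300, 500) unlabeled and the 500 boundary
ambiguous. The classifier here is total: an explicit *borderline* band
covers [300, 500), *medium* starts at exactly 500 (closed) and ends at
1200 (closed), *critical* is strictly above 1200. Band edges are pinned by
boundary tests at ±ε. "Critical" is the same band that clinical prose
sometimes calls "high risk"; the synonymy is deliberate.

## MBL measurement

MBL is the Euclidean distance between the user-marked implant-platform
point and defect-bottom point, scaled by `mm_per_pixel`
(= known length / pixel distance between two calibration points, typically
the implant of known length). Euclidean rather than vertical projection
because images are pre-aligned to the implant axis, making the two nearly
identical, and Euclidean is robust to residual tilt; a projection mode
exists. Per-implant MBL defaults to the worst (max) of mesial/distal,
configurable to the mean.

## Axis alignment

Rotation uses bilinear interpolation; the output frame covers the whole
rotated image and out-of-frame pixels carry a −1 sentinel that is never
valid grey data, so no fabricated texture can enter an ROI (ROIs touching
sentinel pixels raise). Multiples of 90° are exact index remaps. The θ
then −θ round trip reproduces interior pixels of smooth images to about a
grey level; this cannot hold for white-noise images, whose
above-Nyquist content no interpolant preserves.

## Phantom generator

White Gaussian noise smoothed with an isotropic Gaussian kernel, then
affinely mapped to grey levels. The corticalization parameter `c ∈ [0, 1]`
interpolates the kernel width from 1 px (trabecular-like speckle) to 5 px
(corticalized smoothness — matching the 5-pixel analysis offset so that
lag-5 correlation rises with `c`), raises the mean density from 90 to 210
grey levels (gain 120), and damps structured contrast by up to 50%
(corticalized bone is more uniform). Acquisition noise SD 2 grey levels.
These choices follow from the construction's purpose — monotone,
well-separated texture regimes on an 8-bit scale — and make the
phantom → features → CI pipeline strictly increasing in `c` (checked over
50 seeds per level). The phantoms claim no histological or
projection-physics realism: passing pipeline tests shows the texture
machinery responds correctly to controlled correlation/density changes,
not that clinical radiographs behave identically.

## Cohort generator

Per-implant values at 0/3/60 months of functional loading:

- `CI3 ~ Gamma(shape 2, scale 105)` — right-skewed, mean 210, SD ≈ 149,
  matching the reported 3-month cohort moments.
- `CI60 = CI3 · LogNormal(log 1.30, 0.30)` — positive CI3–CI60 dependence
  with mean ratio ≈ 1.32, targeting the reported 60-month mean ≈ 278.
- `MBL60 = max(0, 0.73 + 0.0025·max(0, CI3 − 300) + N(0, 0.30))` — a
  piecewise-linear (hinge) dependence with changepoint κ = 300, because
  the clinical description is threshold behaviour (low risk below 300,
  elevated above 500), not a global linear trend. The intercept is the
  reported low-stratum 60-month mean (0.73 mm).
- `MBL3 = max(0, N(−0.30, 0.80))` — small, CI-independent (no significant
  3-month group difference), mean ≈ 0.19 mm.
- Mesial/distal ROI values scatter around the implant CI with SD 20;
  optional uniform dropout removes implants from the 60-month visit.

**Noise level.** The latent MBL noise default (0.30 mm) is set by the
generator's identifiability contract: the hinge model's slope and
changepoint must be recoverable from a 1000-implant cohort (slope within
15%, κ within 50 CI units). Monte Carlo shows the efficient estimator's
sampling SD scales with the latent noise and exceeds those bands once the
noise approaches a clinical cohort's marginal MBL spread (≈1.3 mm) — that
spread also contains measurement error and between-patient heterogeneity
this generator deliberately does not model. Consequence: simulated MBL
SDs are tighter than clinical ones, and power results on simulated
cohorts overstate clinical power.

## Changepoint fit

Because observed MBL is clamped at zero, zeros are left-censored, and OLS
on the clamped response attenuates the slope well beyond the recovery
bands. The fit therefore maximizes the censored-Gaussian (Tobit)
likelihood: exact-density terms for positive MBL, `Φ(−μ/σ)` terms for
zeros. κ is profiled over a 61-point grid between the 5th and 95th CI
percentiles (BFGS on `(b0, b1, log σ)` at each candidate; log-σ keeps the
scale positive), then refined by bounded scalar minimization between the
neighbouring grid cells (tolerance 0.5 CI units). Starting values come
from hinge-OLS moments. `predict` returns `E[max(0, MBL*)]`, which is
monotone in CI.

## Statistical machinery

- Test choice is normality-gated: Shapiro–Wilk at α = 0.05 on both
  samples selects the parametric branch (paired/Welch t) over the rank
  branch (Wilcoxon signed-rank / Mann–Whitney U). The gate is a fixed,
  documented policy; samples above Shapiro's n limit are thinned.
- Identical paired samples short-circuit to p = 1: no test statistic is
  defined at zero variance, and the evidential content is "no change".
- The stratified contrast compares 60-month MBL between implants with
  3-month CI < 300 and > 500, dropping the borderline band, mirroring the
  two-group clinical comparison.
- Regression bands are standard OLS pointwise 95% intervals from
  statsmodels: the confidence band bounds the conditional mean, the
  prediction band a new observation; the latter contains the former
  pointwise by variance decomposition.
- No multiple-testing correction by default (each test reported at its
  own p-value, matching common clinical reporting); a Holm step-down mode
  is available behind a flag.
- Default correlation is Spearman (CI and MBL are right-skewed); Pearson
  is available.

## Problem sizes and determinism

Test and acceptance runs use: 1000 random ROIs (≤ 20×20, Ng ≤ 16,
d ∈ {1, 2, 5}, all four directions) for exact oracle equivalence; 50
phantom seeds per corticalization level at 64×64; 1000-implant cohorts
(one for parameter recovery, 100 replicates for the stratified contrast);
200 simulated regressions for band coverage. All randomness flows through
seeded `numpy` generators; every synthetic output records its seed, and
identical parameters + seed reproduce outputs byte-for-byte.

## Known limitations

- ROI placement is user-supplied (CSV) or config-driven; there is no
  implant detection or segmentation.
- The exact ROI geometry of the clinical standardization protocol is not
  public; the default 50 × 30 px rectangle at the implant neck is a
  documented, configurable stand-in.
- Only the three CI primitives are implemented, not a full radiomics
  catalogue.
- Simulated cohorts are single-level (no patient clustering, no
  multivariable adjustment) and their MBL noise is tighter than clinical
  spread (see above).
- DICOM support covers single-frame grayscale images; stored values are
  used as-is (no window/level), since texture features must see raw
  optical density.
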