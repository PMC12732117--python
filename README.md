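# corticalization

Radiographic texture scoring of peri-implant bone and 5-year
marginal-bone-loss risk stratification.

## The problem

After a dental implant is loaded, the trabecular (spongy) bone around the
implant neck can transform into denser, more uniform, radio-opaque
cortical-like bone — *corticalization*. On intraoral radiographs this shows
up as a texture change: less grey-level scatter, longer uniform runs,
higher optical density. Corticalization at 3 months of functional loading
is predictive of marginal bone loss (MBL) — the drop of the bone crest from
the implant platform — years later.

This package is for dental radiology and implantology researchers who want
to compute the **Corticalization Index (CI)** on rectangular regions of
interest (ROIs) at the mesial/distal implant neck, classify implants on the
associated risk scale, measure MBL on calibrated radiographs, and analyze
longitudinal cohorts. Because clinical radiographs are rarely shareable,
the package also ships a synthetic bone-texture phantom generator and a
longitudinal cohort simulator, so the entire pipeline runs end-to-end
without any external data.

## The index

For an ROI quantized to `Ng` grey levels, with a grey-level co-occurrence
matrix (GLCM) taken at a 5-pixel offset and a grey-level run-length matrix
(GLRLM):

- **Difference entropy** — Shannon entropy (common logarithm) of the GLCM
  difference distribution `p_{x−y}`:

  `DifEntr = − Σ_{i=0}^{Ng−1} p_{x−y}(i) · log10 p_{x−y}(i)`

- **Long-run emphasis** — the k²-weighted mean run length:

  `LngREmph = Σ_i Σ_k k² p(i,k) / Σ_i Σ_k p(i,k)`

- **Mean optical density (MOD)** — the mean raw grey value of the ROI.

The composite index is

  `CI = LngREmph · MOD / DifEntr`

and the risk scale on the 3-month CI is: **low** < 300 ≤ *borderline*
< 500 ≤ **medium** ≤ 1200 < **critical**. (The borderline band makes the
published scale total; thresholds are configurable.) Absolute CI
magnitudes depend on the texture conventions — grey-level depth, offset
direction, log base — which the package records in every output.

## Worked example

```python
import corticalization as cz

for label, c in [("trabecular (c=0.1)", 0.1), ("corticalized (c=0.9)", 0.9)]:
    img = cz.generate_phantom(cz.PhantomParams(size=(64, 64), corticalization=c, seed=7))
    f = cz.compute_features(img.pixels)
    ci = cz.corticalization_index(f)
    print(f"{label}: DifEntr={f.dif_entr:.4f}  LngREmph={f.lng_r_emph:.3f}  "
          f"MOD={f.mean_optical_density:.1f}  CI={ci:.1f}  risk={cz.classify_risk(ci).label}")
```

prints

```
trabecular (c=0.1): DifEntr=1.4396  LngREmph=1.308  MOD=101.8  CI=92.5  risk=low
corticalized (c=0.9): DifEntr=1.3228  LngREmph=1.559  MOD=188.5  CI=222.2  risk=low
```

— the corticalized phantom has lower difference entropy (less scatter),
longer runs and higher density, so its CI is 2.4× the trabecular one.

Cohort analysis on simulated data:

```python
df = cz.generate_cohort(cz.CohortParams(n_implants=1000, seed=1))
print(cz.summarize_visits(df).round(2).to_string(index=False))
res = cz.ChangepointMBLModel.from_cohort(df).fit()
print(res.summary())
```

```
 visit_months    n  ci_mean  ci_sd  mbl_mean  mbl_sd
            0 1000   176.93 137.19      0.00    0.00
            3 1000   206.48 144.78      0.20    0.36
           60 1000   281.80 219.36      0.79    0.36
Censored hinge regression: MBL ~ max(0, CI - changepoint)
  n observations : 1000
  log-likelihood : -211.92
  intercept      :   0.7179 mm
  slope          :  0.00265 mm per CI unit
  changepoint    :    306.8 CI units
  sigma          :   0.2967 mm
```

The fitted changepoint (≈307 CI units) and slope recover the generator's
true values (300, 0.0025): 60-month bone loss starts to climb once the
3-month CI passes ≈300. The stratified contrast on the same cohort gives a
low-CI-stratum mean of 0.72 mm versus 1.52 mm above CI 500
(Mann–Whitney p ≈ 1.6e−28).

MBL measurement is two marked points plus a calibration:

```python
mm = cz.calibrate_mm_per_pixel(10.0, (40, 100), (240, 100))  # 10 mm implant over 200 px
cz.measure_mbl((40, 100), (60, 105), mm).mbl_mm              # -> 1.031 mm
```

## Command line

```bash
ci extract  --image xray.png --roi rois.csv --out patches/
ci features --patches patches/ --ng 64 --distance 5 --out features.csv
ci score    --features features.csv --out report.csv
ci mbl      --landmarks points.csv --mm-per-pixel 0.05 --out mbl.csv
ci simulate cohort --n 1000 --seed 7 --out cohort.csv
ci analyze  --cohort cohort.csv --out report.json
```

## Layout

- `src/corticalization/image_io.py` — PNG/TIFF/DICOM reading, implant-axis
  alignment, ROI extraction
- `src/corticalization/texture.py` — quantization, GLCM + difference
  entropy, GLRLM + long-run emphasis
- `src/corticalization/index.py` — the CI and the risk scale
- `src/corticalization/mbl.py` — calibration and MBL measurement
- `src/corticalization/synthetic.py` — phantoms and cohort simulation
- `src/corticalization/changepoint.py` — censored hinge regression of MBL
  on CI (statsmodels-style Model/Results)
- `src/corticalization/analysis.py` — cohort statistics and 95% bands
- `docs/methods.md` — models, assumptions, parameter choices, limitations
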