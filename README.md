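# peatspec

Quantitative analysis of ATR-FTIR spectra of peat and plant organic matter.

Attenuated-total-reflectance FTIR is a fast, cheap probe of solid-phase
organic matter chemistry, but it is only semi-quantitative: overall
absorbance varies with sample matrix and instrument contact, so spectra are
usually compared via band ratios (humification indices), which cannot say
*which* compound class changed. `peatspec` implements an alternative
statistic, the **normalized corrected peak height**, and the calibration and
trend statistics built on it, for researchers studying peat decomposition
and humification along climatic gradients.

## The method

For each target band (carbohydrates ~1030 cm⁻¹; aromatic ring stretches
~1510 and ~1630 cm⁻¹; aliphatic C–H ~2850 and ~2920 cm⁻¹), per sample:

1. **Endpoint detection.** Each endpoint is the local absorbance minimum in
   an expected wavenumber window; if the window is monotone (no minimum),
   the point maximizing the discrete second derivative is used instead.
2. **Baseline correction.** A straight line is drawn between the endpoint
   absorbances; the corrected signal is the absorbance above that line, and
   the peak height *h* is its maximum between the endpoints.
3. **Area normalization.** The normalized corrected height is
   *h* / ∫A(ν̃)dν̃, the height divided by the total integrated (trapezoidal)
   area of the spectrum, removing matrix- and instrument-induced scaling.

Normalized heights are calibrated to wet chemistry by ordinary least
squares on a reference set of plant and paper standards:
% cellulose + hemicellulose = a·carb + b, and
% Klason lignin = a·(arom15 + arom16) + b, the summed aromatic predictor
being chosen among {arom15, arom16, sum} by fit quality. Per-sample
prediction uncertainty is the calibration's standard error of the
y-estimate, SEE = √(SSE/(n−2)). Glossy-magazine standards (clay band
overlapping the carb peak) are excluded from the carbohydrate fit and
office-paper standards (delignified pulp) from the aromatic fit.

Downstream statistics cover the transect workflow: per-core surface
(≤ 50 cm) means ± SD, OLS of those means on latitude or mean annual
temperature, pooled-variance t contrasts between sample groups, LOESS
(degree 2, span 0.75, tricube) depth profiles split at 45°N, PCA of spectra
rescaled to integrated area 100, and least-squares fitting of external
variables onto the score plane with permutation significance. An advisory
screen flags probable silicate interference (kaolinite doublet at
3695/3620 cm⁻¹ or the 780 cm⁻¹ band, together with a large 1030 cm⁻¹ peak).

A synthetic-data module generates Gaussian band-mixture spectra whose
normalized band heights encode known compositions, plus full calibration
sets and latitudinal transects, so the entire pipeline can be validated
against ground truth.

## Worked example

```python
from peatspec import (
    generate_calibration_set, calibrate_from_standards,
    TransectParams, generate_transect, PeakHeightTransformer,
    build_composition_table, surface_summary, latitudinal_regression,
)

standards = generate_calibration_set(seed=0)          # 58 synthetic standards
models = calibrate_from_standards(standards)
carb, arom = models["carbohydrates"], models["aromatics"]
print(f"carbohydrates: slope={carb.slope:.0f} R2={carb.r_squared:.2f} "
      f"SEE={carb.see:.1f} wt% (n={carb.n})")
print(f"aromatics ({arom.predictor}): slope={arom.slope:.0f} "
      f"R2={arom.r_squared:.2f} SEE={arom.see:.1f} wt% (n={arom.n})")

spectra, records = generate_transect(TransectParams(seed=0))
heights = PeakHeightTransformer().fit_transform(spectra)
table = build_composition_table(heights, records, models)
peat = table[table["material"] == "peat"].copy()
peat["core_id"] = peat["site"]
summ = surface_summary(peat)
summ = summ.merge(peat.groupby("site")["latitude_deg"].first(),
                  left_on="core_id", right_index=True)
trend = latitudinal_regression(summ, "latitude_deg", "mean_carbohydrates_est")
print(f"surface carbohydrates vs latitude: slope={trend.slope:.3f} wt%/deg "
      f"(R2={trend.r_squared:.2f}, p={trend.p_value:.1e}, n={trend.n} cores)")
```

Output:

```
carbohydrates: slope=9440 R2=0.79 SEE=8.7 wt% (n=54)
aromatics (arom15_plus_arom16): slope=8319 R2=0.62 SEE=5.3 wt% (n=54)
surface carbohydrates vs latitude: slope=0.308 wt%/deg (R2=0.95, p=9.8e-08, n=12 cores)
```

Reading this: the carbohydrate calibration explains 79% of the variance in
wet-chemistry % cellulose + hemicellulose across 54 standards (4 OMG
standards excluded), with a per-sample uncertainty of ±8.7 wt%; the summed
aromatic predictor wins the aromatic calibration; and on the synthetic
12-core transect (generated with a latitudinal slope of 0.4 wt%/degree and
5 wt% per-sample noise) the recovered surface trend of 0.308 wt%/degree is
a strongly significant increase of carbohydrates toward the poles.

The calibration is also available as a scikit-learn regressor
(`LinearPeakCalibration`, with `slope_`, `intercept_`, `r_squared_`,
`see_` fitted attributes), and `PeakHeightTransformer` /
`AreaNormalizedPCA` / `LoessSmoother` follow the fit/transform/predict
conventions, so the pieces compose with sklearn pipelines.

## Command line

```sh
peatspec convert --from-transmittance in.csv out.csv
peatspec measure --out measurements.csv --flag-silicates spectra/*.csv
peatspec calibrate --standards standards.csv --out models.json
peatspec predict --models models.json heights.csv --out composition.csv
peatspec simulate transect --seed 1 --out data/
peatspec run --config run.yml --out report/
```

`peatspec run` executes the full workflow (measure → screen → calibrate →
predict → analyze) from a YAML config with declarative sample exclusions,
writing CSV report tables and a JSON manifest that records the seed, a
config hash, and the included/excluded status of every sample.

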