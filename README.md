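# effortshift

Spatiotemporal analysis of climate-linked redistribution of tropical-tuna
purse-seine fishing effort in the eastern Atlantic (29°N–30°S, 35°W–19°E).

Pelagic fleets follow their target species, and tropical tunas follow the
water masses they prefer — so a warming ocean can show up first not in
surveys but in *where the boats fish*. `effortshift` implements, as a
tested and reusable pipeline, the statistical machinery needed to detect
and attribute such shifts from gridded monthly effort/catch records and
gridded sea-surface-temperature anomalies (SSTA):

1. **Centre of gravity (COG).** The annual effort-weighted mean latitude
   per hemisphere,

   `COG = Σᵢ latᵢ·effortᵢ / Σᵢ effortᵢ`,

   with an OLS trend test and Pearson correlation against regional SSTA.

2. **DINEOF gap filling.** Quarterly 5°×5° effort-anomaly series with
   < 25 % missing data are reconstructed by Data Interpolating EOFs:
   iterative truncated-SVD imputation with the rank chosen by
   cross-validation on hidden observed entries.

3. **EOF decomposition.** Empirical orthogonal functions of the effortA
   and SSTA covariance matrices give spatial modes `eᵢ`, principal
   components `PCᵢ`, explained-variance fractions `100·λᵢ/Σλ`, and the
   per-cell local explained variance

   `LCⱼᵢ = eⱼᵢ² λᵢ / Σ_{k≤kmax} λₖ eⱼₖ²`.

   Cross-correlating the leading PCs of effortA and SSTA tests whether
   the dominant mode of effort redistribution tracks temperature.

4. **Random-forest attribution.** Because management, access agreements
   and technology also move fleets, quarterly effort and the effortA PC1
   are regressed (1000-tree forests, `mtry = p/3`, OOB scoring) on seven
   drivers: SSTA, calendar quarter, % catch on FADs, TAC flag, time-area
   closure flag, and the number of fisheries partnership agreements
   (SFPAs) and of vessels they admit — with %IncMSE permutation
   importance, partial-dependence curves, and GVIF collinearity
   screening.

A first-class synthetic-data generator (`effortshift.synthetic`) emulates
all three inputs with *known* spatial modes, PC correlations, COG drift,
missingness and driver effects, so that every statistic the pipeline
reports can be checked against ground truth. Real ICCAT/Kaplan-style
files can be supplied through the documented CSV/NetCDF formats instead.

## Worked example

```python
from effortshift import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(seed=5)).stats
print(f"SSTA EOF1 variance:    {summary['ssta_eof_var_frac'][0]:.1f}%")
print(f"effortA EOF1 variance: {summary['effort_eof_var_frac'][0]:.1f}%")
print(f"PC1 correlation:       r = {summary['pc1_correlation_r']:.2f} "
      f"(p = {summary['pc1_correlation_p_value']:.1e})")
print(f"southern COG trend:    {summary['cog_south_slope_deg_per_year']:+.3f} deg/yr "
      f"(p = {summary['cog_south_trend_p_value']:.1e})")
```

prints

```
SSTA EOF1 variance:    70.1%
effortA EOF1 variance: 20.6%
PC1 correlation:       r = 0.48 (p = 2.0e-07)
southern COG trend:    -0.049 deg/yr (p = 4.1e-11)
```

Under the default synthetic conditions the generator injects a 70 %
leading SSTA mode, a 19 % leading effortA mode, a PC1 cross-correlation
of 0.5 and a −0.05 °/yr southern COG drift; the run above recovers all
four through the complete ingest → anomaly → DINEOF → EOF → COG chain
(the effortA fraction reads slightly high because DINEOF-reconstructed
entries carry less white noise than observed ones). The same analysis is
available from the shell:

```sh
effortshift simulate --seed 5 --out data/        # effort.csv, ssta.csv, covariates.csv
effortshift cog --input data/effort.csv --hemisphere south
effortshift run --seed 5 --out results/          # full pipeline, JSON summary
```

## Layout

| module | role |
| --- | --- |
| `effortshift.grid_ingest` | CSV/NetCDF readers, region subsetting, quarterly aggregation, deseasonalisation, regional series, trends |
| `effortshift.cog_analysis` | hemispheric centre-of-gravity series, trends, correlations |
| `effortshift.dineof` | reconstructable-series selection and DINEOF gap filling |
| `effortshift.eof_core` | EOF decomposition, local explained variance, PC correlation |
| `effortshift.driver_models` | GVIF screening, random forests, %IncMSE, partial dependence |
| `effortshift.synthetic` | synthetic effort/SSTA/covariate generator with ground truth |
| `effortshift.pipeline` / `effortshift.cli` | orchestration, run summaries, `effortshift` CLI |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
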