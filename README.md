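# agrisuit

Agro-climatic crop-suitability modelling for rain-fed farming systems:
where can a crop sustain production today, and how does that geography shift
under projected climate change?

The package is aimed at climate-impact and agricultural-adaptation analysts
who have daily gridded weather, a soil-carbon grid and district-level yield
statistics, and want national maps of ordinal crop suitability — for single
crops and for crop portfolios — under current and scenario climates.  A
seeded synthetic-data module emulates every input (CHIRPS-like daily
precipitation with a unimodal north / bimodal south seasonal cycle,
WFDEI-like min/max temperature, a cropland mask, district partitions,
multi-year yield tables with a known driver), so the full pipeline is
testable end to end with no downloads.

## Method

1. **Predictors.** Eight biophysical variables are derived per pixel from
   daily weather: growing-season rainfall sum (24 May–30 Sep in the north,
   1 Mar–30 Jun in the south), March–September rainfall sum, sowing-window
   rainfall sum, the coefficient of variation of March–September monthly
   rainfall (%), mean diurnal temperature range, growing-season and
   March–September mean temperature, and topsoil organic carbon.
2. **Classes.** District mean yields ȳ_d over the record are quartered by
   their 25th/50th/75th percentiles into four ordinal suitability classes:
   limited (1) < marginal (2) < moderate (3) < optimal (4), with optimal
   defined by ȳ_d ≥ q75 and limited by ȳ_d < q25.  Every crop-masked pixel
   inherits its district's class.
3. **Model.** One XGBoost multiclass (softmax objective, probability
   output) model per crop maps the eight predictors to the four classes.
   Samples are split 70/30 stratified by class; boosting rounds, maximum
   depth and learning rate are tuned by cross-validated grid search.
4. **Evaluation.** From the held-out confusion matrix *C* (rows =
   reference): overall accuracy OA = tr(C)/n; Cohen's κ = (p_o − p_e)/(1 −
   p_e) with p_e from the marginals; the pairwise-average (Hand–Till)
   multiclass AUC, Â = mean over class pairs {i,j} of ½[A(i|j) + A(j|i)];
   and eleven one-vs-rest per-class metrics.  Variable importance is
   normalized total split gain.
5. **Scenarios.** Per-GCM national climate deltas (four GCMs × RCP2.6/8.5)
   are added to the baseline predictors (rainfall clipped at 0, soil
   unchanged) and the fitted models are re-applied to map future
   suitability; area-change tables difference future against current class
   areas, averaged across GCMs.
6. **Multi-crop scores.** Stacked class maps give per-pixel counts of crops
   at each level, a four-crop rank sum on a 4 (very low) – 16 (very high)
   scale, and two-crop sums on 2–8 with categorical labels (Ld-Ld … Op-Op).

## Worked example

The parameter-recovery experiment builds a synthetic study in which each
pixel's class is a noisy monotone function of growing-season rainfall, with
the noise calibrated so the Bayes-optimal classifier (known in closed form
from the generator) scores 85% accuracy:

```python
from agrisuit.recovery import recovery_experiment
r = recovery_experiment(seed=1)
print(f"Bayes oracle accuracy : {r.bayes_accuracy:.3f}")
print(f"held-out OA / kappa   : {r.oa:.3f} / {r.kappa:.3f}")
print(f"held-out AUC          : {r.auc:.3f}")
print(f"top variable, share   : {r.top_variable}, {r.top_share:.3f}")
```

```
Bayes oracle accuracy : 0.850
held-out OA / kappa   : 0.853 / 0.804
held-out AUC          : 0.975
top variable, share   : rain_growing_season, 0.991
```

The model recovers essentially all attainable signal — held-out accuracy
sits at the Bayes bound (it cannot exceed it beyond sampling noise), chance-
corrected agreement is high, and 99% of the ensemble's split gain lands on
the variable that actually generated the classes.

The bundled multi-model delta table summarizes as:

```bash
$ agrisuit deltas --scenario RCP2.6
scenario             variable   mean  mean_rounded  n_models  sign_agreement
  RCP2.6  rain_growing_season 17.750          17.8         4               3
  RCP2.6         rain_mar_sep 15.750          15.8         4               2
  ...
```

e.g. March–September rainfall changes by +15.75 mm on the four-model mean
(+16 mm at integer reporting precision), with only two of four GCMs
agreeing on the sign — rainfall projections are far less consistent than
the temperature rows, which warm in all four models.

The full pipeline (`agrisuit run-all --seed 1 --out runs/demo` or
`agrisuit.run_pipeline`) emits, per crop: thresholds, label and suitability
rasters, a fitted model, metrics and importance CSVs; per scenario: future
suitability maps and area-change tables; plus multi-crop score maps, count
tables and a manifest of artifact hashes for reproducibility.

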