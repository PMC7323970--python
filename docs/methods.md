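# Methods

This note documents the models, conventions and design choices behind
`agrisuit`, in the order the pipeline runs.

## Synthetic inputs

The generator produces the structures of the real data streams a national
suitability analysis consumes, not their full climatology.

**Daily weather.** Precipitation follows a deterministic seasonal mean rate
`base + amplitude · kernel(doy)` per climatic zone, where the kernel is a
sum of Gaussian bumps over day-of-year: one bump centred in August for the
northern (unimodal monsoon) zone, two bumps centred in May and October for
the southern (bimodal) zone.  When a zone's March–September rainfall target
is set, the amplitude is solved so the expected 1 Mar–30 Sep sum equals the
target.  Each pixel gets smooth, month-specific lognormal wetness
multipliers (mean 1, log-sd 0.25 by default, independent across months), so
different seasonal windows carry partially independent spatial signal —
which is what makes single-driver recovery experiments identifiable.  Daily
noise is additive Gaussian with sd proportional to the day's mean rate
(factor 0.5), truncated at zero; because the sd scales with the mean, dry
days stay dry and the truncation bias on window sums is below 1%, keeping
realized zonal March–September sums within a few percent of their targets.

Temperature is a single annual harmonic (hottest mid-March, amplitude
1.8 °C) anchored so the March–September mean of the daily mean temperature
equals the configured value, plus a smooth pixel offset field and daily
noise.  The diurnal range is generated directly (`tmin/tmax = tmean ∓
dtr/2`) with `dtr = max(0, dtr_clim + noise)`, which guarantees
`tmax ≥ tmin` everywhere.

**Default calibration.** North target 1050 mm and south target 1442 mm give
a national March–September mean of ~1246 mm on an equal-area two-zone
domain; diurnal range 9.9 °C and March–September mean temperature 25.7 °C
match the same national current-climate summary; 11 years starting 2006;
0.05° grid spacing.  These constants were fixed once from the published
national baseline row.  The generator does **not** attempt to reproduce the
within-season partition of rainfall (its growing-season sums exceed the
published national growing-season figure), interannual autocorrelation,
drought spells, or orographic structure — so passing tests demonstrate
correctness of the derivations and recovery of planted signal, not skill on
real climate fields.

**Region.** Districts partition the masked pixels by nearest-seed (Voronoi)
growth from randomly placed seed pixels: contiguous-ish, guaranteed
non-empty.  Zone is north at/above a split latitude.  Soil carbon is a
smooth non-negative random field (mean 30 t/ha, sd 8).

**Yields.** District-year yields are `response(district mean of the chosen
driver) + N(0, sd)` truncated at zero, with `response` any deterministic
monotone map.  With sd 0 the table is an exact function of the driver — the
oracle that downstream recovery tests rely on.

All randomness descends from one root seed through named, CRC-derived
substreams, so adding a component never perturbs another's draws.

## Predictor derivation

Windows are calendar month/day intervals resolved per year, then annual
statistics are averaged over years.  The printed day-of-year annotations in
the source table are internally inconsistent with its own calendar dates
(e.g. 24 May is DOY 144 in non-leap years, not 145); the calendar dates are
taken as authoritative.  The northern "sowing month" window is 24 May–30
June (38 days), as printed.  Daily mean temperature is `(tmax + tmin)/2`,
since the emulated sources provide only min/max.  The rainfall CV pools all
year × month sums (7 × n_years values) and uses the sample standard
deviation (ddof 1); both are configurable (`ddof=0`, `pooled=False`)
because the original convention is unstated.  Pixels with zero mean monthly
rainfall have an undefined CV and are returned as NaN with a warning, which
also excludes them from modelling.  Grid-cell means over masked pixels use
NaN-aware reductions.

## Classing

Percentiles use linear interpolation between order statistics (numpy
default; nearest-rank available).  Class intervals are half-open from
below with optimal closed at q75 — the verbal definitions ("above",
"between", "under") leave exact boundaries open, and for continuous yields
any convention differs on a measure-zero set.  Thresholds are computed per
crop over all districts nationally.  Training examples are pixels (each
masked pixel inherits its district's class); this pseudo-replicates
district information across pixels, which is the point of the
per-pixel assignment but worth remembering when interpreting skill.

## Model

XGBoost with the softmax multiclass objective in its probability variant
(`multi:softprob`): hard labels are the argmax, so predictions match the
hard-label objective while class probabilities remain available for the
multiclass AUC.  The 70/30 split is stratified by class so all four classes
appear in both partitions (disable with `stratify=False`).  The tuning grid
covers boosting rounds {50, 100, 200}, maximum depth {2, 4, 6} and learning
rate {0.05, 0.1, 0.3} with 5-fold stratified CV maximizing accuracy; all
are overridable.  The learning rate is tuned as the third axis alongside
rounds and depth — a "sigma" is not a parameter of gradient-boosted trees.
Training is forced single-threaded (`nthread=1`, `tree_method="hist"`) so
fitted models and all downstream artifacts are bit-reproducible under a
fixed seed.

## Evaluation

All metrics are computed from first principles on the K×K confusion matrix
(rows = reference).  κ is undefined when chance agreement p_e = 1; that
only occurs when every count sits in one diagonal cell, where 1.0 is
returned.  Zero-denominator per-class ratios (e.g. PPV when a class is
never predicted) are reported as NaN with a warning, never silently as 0.
The multiclass AUC is the pairwise-average construction: for each unordered
class pair (i, j), A(i|j) is the rank-statistic (Mann–Whitney, ties 0.5)
AUC of the class-i probability restricted to samples of classes i and j,
the pair contributes ½[A(i|j)+A(j|i)], and pairs are averaged.  Probability
scores, not hard labels, feed the AUC — hard-label AUC degenerates.

## Importance

"Standardized between 0 and 1" is read as shares summing to 1 (total split
gain per variable divided by the grand total); a max-normalized variant is
available.  Two groupings are reported because the field's prose convention
is ambiguous about whether rainfall variability belongs with the rainfall
sums: `GROUPS_RAIN4` (CV inside rainfall) and `GROUPS_RAIN3` (CV as its own
group).  Neither is privileged.

## Scenarios

Deltas are additive for every variable, uniform in space by default
(national summaries), with a gridded mode for users holding per-pixel delta
rasters.  Rainfall fields and the CV are clipped below at zero after
shifting; soil carbon is held constant, as no near-future projections exist
for it.  Applying a delta is exactly one double-precision addition per
pixel, so `future` is bit-for-bit equal to `baseline + delta` wherever no
clipping occurs.  Multi-model summary cells are rounded half-up (via
`decimal`, not banker's rounding) at the reporting precision — integer mm
reproduces e.g. a mean of 15.75 as +16.  Note that four of the fourteen
published summary cells for these deltas (RCP8.5 sowing rain, CV,
growing-season rain, and Mar–Sep temperature) cannot be reproduced from the
published per-model rows at any rounding convention; the source evidently
averaged unrounded per-model values.  This package reports the mean of the
values actually supplied, which for those cells gives 13.8, 2.5, 17.3 and
2.4 respectively.

Sign agreement counts the models whose delta shares the sign of the
multi-model mean (models at exactly zero count only when the mean is zero).

## Multi-crop aggregation

Scores are purely additive rank sums; no agronomic interaction
(nitrogen fixation, water competition, pollination) is modelled.  A pixel
where any crop map is no-data is no-data in every aggregate.  Cell areas
default to a uniform nominal value (30.25 km² ≈ a 0.05° cell near the
equator) with an optional latitude-cosine mode normalized to preserve the
domain-mean cell area.  Change tables report percentage points of domain
area and km², averaged across GCMs when several futures are supplied;
conservation (percentages sum to 100, per-class point changes sum to 0) is
exact up to floating-point rounding.  Multi-crop count tables map the four
suitability levels to counts of crops at that level, the only reading
consistent with comparing "moderate suitability for at least k crops"
statements against a count table.

## Recovery experiment and problem sizes

The validation harness plants a class signal on one driver: latent
`z = driver + N(0, σ)`, classes are the quartile bins of z, and σ is
bisected so the Bayes rule — computable exactly from the generator —
achieves 85% accuracy.  The default experiment uses a 40 × 50 grid (2000
pixels), 11 years of daily weather, the full tuning grid and 5-fold CV; the
end-to-end pipeline exercised in tests and in `scripts/acceptance.py` uses
a 16 × 18 grid, 3–4 years and a reduced grid, sizes chosen to keep the
demonstration compact while leaving every stage non-trivial (the larger
recovery experiment is where skill claims are measured).

## Known limitations

- The synthetic domain is an idealized two-zone rectangle; no real
  administrative boundaries, cropland product or bias-adjusted climate
  fields are used, and headline national percentages from any real-world
  study are out of reach by construction.
- Raster output is plain multi-band TIFF with a JSON sidecar for axes and
  band names rather than georeferenced GeoTIFF; NetCDF output is classic
  (NetCDF-3) format.
- Pixel-level training inherits district-level labels (pseudo-replication);
  an analyst wanting district-level inference should aggregate predictors
  to districts before fitting.
- No spatial cross-validation; skill estimates on spatially autocorrelated
  fields are optimistic in the way standard random splits always are.
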