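# urbanshift

Climate-driven turnover forecasting for urban wildlife: presence-background
niche models with bias correction, tuned by spatial-block cross-validation
and the continuous Boyce index, projected onto city quadrats under future
emission scenarios, with gains/losses/extirpation accounting and
negative-binomial summaries on top.

## Who this is for

Macroecologists and urban ecologists who want to ask: *given where a species
has been recorded and how the climate will change, which cities does it
leave, and which does it newly reach?* The package implements the full
pipeline — from raw occurrence records to per-city species turnover tables —
and ships a synthetic-world generator so every stage can be tested against
virtual species with known Gaussian niches, without downloading anything.

## The model

The core is an L1-regularized maximum-entropy (MaxEnt) niche model for
presence-background data. With features `f(x)` expanded from climate
variables (linear, quadratic, pairwise product, hinge and threshold
transforms on `[0, 1]`-rescaled values) and linear predictor
`η(x) = Σ_f β_f f(x)`, fitting minimizes the convex penalized conditional
negative log-likelihood

```
J(β) = log Σ_bg exp(η(x_j)) − mean_pres η(x_i) + Σ_f λ_f |β_f|
```

where `λ_f = r · β_class(n_pres) · sd_f / √n_pres` follows the published
MaxEnt default regularization schedule and `r` is the tuning multiplier. At
`λ = 0` the optimum satisfies exact moment matching: the fitted
distribution's feature expectations equal the presence-sample means.
Suitability is reported on the logistic scale
`τ e^H e^{η−offset} / (1 − τ + τ e^H e^{η−offset})` with prevalence
`τ = 0.5` and `H` the entropy of the fitted background distribution.

Per species the pipeline: cleans records (ocean, bounds, duplicates,
recency window), applies the ≥10-records-per-city filter, spatially thins to
one record per 25 km cell, restricts background points to a buffered convex
hull of the presences, prunes collinear climate variables (greedy pairwise
|r| > 0.7), cross-validates all 48 candidate models (8 feature-class sets ×
6 regularization multipliers) on quadrant spatial blocks, selects the
highest mean continuous Boyce index, thresholds at max(sensitivity +
specificity), and gates out species with n < 10, no best model, or training
AUC < 0.70. Kept models are projected onto a stratified 10×10 grid of 100
points per 20×20 km city quadrat for the historic baseline and three future
scenarios (SSP1-2.6, SSP3-7.0, SSP5-8.5), and each species × city cell is
classified as gained, lost, or unaffected.

## Worked example

```bash
urbanshift simulate uw --seed 5 --n-species 8 --n-cities 3
urbanshift run uw/config.yaml
urbanshift evaluate uw/run uw/truth_occupancy.csv
```

prints

```
wrote synthetic study under uw (8 species, 3 cities)
run complete: uw/run
{
 "accuracy": 0.9333333333333333,
 "n_cells": 60,
 "n_species": 5
}
```

meaning 5 of the 8 virtual species survived the quality gate and their
city-presence calls agree with the generator's true occupancy in 93% of the
60 species × city × scenario cells. The turnover table
(`uw/run/turnover_city.csv`) starts

```
city,scenario,gained,lost,unaffected_present,unaffected_absent,historic_richness,future_richness,net
city01,SSP1-26,0,0,2,3,2,2,0
city02,SSP1-26,0,0,3,2,3,3,0
city03,SSP1-26,0,0,3,2,3,3,0
city01,SSP3-70,0,1,1,3,2,1,-1
city02,SSP3-70,0,2,1,2,3,1,-2
```

— under the mild scenario nothing changes, under SSP3-7.0 city02 is
predicted to lose two of its three resident species, and the identity
`net = gained − lost = future − historic` holds on every row. Each fitted
model can be inspected:

```python
from urbanshift.maxent import MaxEntResults
res = MaxEntResults.load("uw/run/models/sp003.json")
print(res.summary())
```

```
Maximum-entropy niche model
===========================
feature classes:     HQ
reg multiplier:      3.0
variables:           MAP, MAT, bio03, bio04
nonzero features:    4 / 68
entropy H:           7.3830
threshold:           0.5178728513324217
mean_train_AUC:      0.8334
mean_test_AUC:       0.7830
mean_BCI:            0.8012
AUC_diff:            0.0504
percent contribution:
  MAT           91.6%
  MAP            7.5%
  ...
```

This species' niche was generated on MAT, and permutation importance
correctly attributes 92% of the model to MAT.

The library surface follows the Model/Results convention:

```python
from urbanshift.maxent import MaxEnt, FeatureSpec
res = MaxEnt(presence_values, background_values, FeatureSpec("LQ", 1.0)).fit()
res.predict(new_values, scale="logistic")
```

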