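# Methods

This note documents the models and procedures implemented in `urbanshift`,
the defaults and why they were chosen, what the synthetic world does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## Niche model

The model is presence-background maximum entropy: the distribution over the
modelled landscape with maximal entropy subject to regularized constraints
that fitted feature expectations match presence-sample means. It is fitted
in its equivalent penalized conditional-likelihood form

J(β) = log Σ_bg e^{η(x_j)} − mean_pres η(x_i) + Σ_f λ_f |β_f|,
η(x) = Σ_f β_f f(x),

a convex problem whose λ→0 KKT condition is exact moment matching; the test
suite checks this against an independent convex optimization.

**Features.** Climate values are rescaled per variable to u = (v − min)/(max
− min) over the training background and clamped to [0, 1] at prediction
time (a clamped transfer is the standard behavior when projecting into
future climates outside the training range). Feature classes: linear (u),
quadratic (u²), product (u_i·u_j for all pairs), hinge (forward
max(0,(u−k)/(1−k)) and reverse max(0,(k−u)/k)) and threshold (1(u>k)) at
`n_hinge_knots` knots evenly spaced in (0, 1). Default knots: 20
(tool-default magnitude); the demo configurations use 8 to keep desk-scale
runs fast. Feature order is deterministic: class letters L, Q, P, H, T,
variables in kept order within a class, knots in order, forward hinges
before reverse.

**Regularization.** λ_f = r · β_class(n_pres) · sd_f / √n_pres, with
β_class interpolated from the published MaxEnt default tables (linear
1.0→0.05, quadratic 1.3→0.05, product 2.6→0.05, threshold 2→1, hinge 0.5
flat, by presence count) and r the tuning multiplier ∈ {0.5, …, 3.0}; r = 0
expresses the unpenalized model used in diagnostics. The tables are in
`maxent._BETA_TABLES` so they are inspectable.

**Output scales.** `raw` is e^{η−offset}, normalized to sum to 1 over the
training background (offset = log-partition). `logistic` is
τ·e^H·raw/(1−τ+τ·e^H·raw) with assumed prevalence τ = 0.5 and H the entropy
of the fitted background distribution; an uninformative model scores 0.5
everywhere. The logistic transform is strictly increasing in η, so
rankings, AUC and the Boyce index are identical on either scale.

**Solver.** Proximal Newton: IRLS outer iterations whose L1-penalized local
quadratic model is minimized by cyclic coordinate descent (numba-JIT'd when
available, with an identical pure-Python fallback), with a KKT working-set
strategy (only nonzero or KKT-violating features enter the quadratic
model; a full KKT sweep certifies the solution), backtracking on the true
penalized objective, and Levenberg-style adaptive damping when the local
model is near-singular. The solver works in background-standardized feature
space — this equalizes curvature across hinge/threshold columns and makes
the per-feature penalty uniform within a class — and the exact raw-space
problem is recovered by rescaling; convergence is judged on the
standardized coefficients (max change < 1e-6, default cap 10,000
iterations). Features with zero background variance are excluded: they
carry no information about the fitted distribution and make the
unpenalized likelihood unbounded.

**Boundedness.** The conditional likelihood is unbounded whenever the
presence feature mean lies outside the convex hull of background feature
vectors. The pipeline therefore adds the presence samples to the background
before fitting (the reference tool's default behavior), which guarantees a
bounded objective; the solver additionally aborts early with a convergence
error if coefficients diverge.

## Pipeline stages and defaults

| stage | rule | default |
|---|---|---|
| record cleaning | drop out-of-bounds, ocean, stale, exact duplicates by (species, x, y, date); precedence bounds → ocean → window → duplicate; first duplicate kept | 10-year window anchored at a config reference date (2020-12-31), not the wall clock |
| city filter | species listed for a city iff ≥ min_n cleaned records in its quadrat (half-open 20×20 km box) | min_n = 10, inclusive |
| thinning | one record per coarse cell anchored at the lattice origin, survivor drawn with the run seed (not "first record", to kill row-order dependence) | 25 km cells |
| background | uniform over land cells inside the buffered convex hull of thinned presences (bounding box if < 3 non-collinear points); presences appended afterwards | n_bg = 10,000 (library), 2,000 (demo); buffer 100 km |
| collinearity | greedy: while any pair |r| > threshold at land sample points, drop the member with the larger mean |r| to the rest (ties: later input order); zero-variance variables dropped first | threshold 0.7 |
| CV folds | quadrants at presence median x/y (SW=1, SE=2, NW=3, NE=4; on-line points go to the lower index); empty quadrant → seeded random k-fold with a warning | k = 4 |
| tuning | all 8 class sets × 6 multipliers = 48 candidates; per candidate, mean held-out Boyce index and AUC over folds; winner = max mean BCI, ties by higher test AUC, lower multiplier, fewer classes; winner refit on all data. The regularization path is walked strong→weak with warm starts | — |
| Boyce index | P/E ratio across overlapping windows vs window center, Spearman; E=0 windows skipped; < 3 windows → NaN (fails the gate); flat P/E → 0 | 101 windows, width 0.1 |
| threshold | max(sensitivity + specificity) over observed scores, presence call at score ≥ t, smallest tie; `equal_sens_spec` (min |sens − spec|) available as a config option | — |
| gate | drop if n < 10, no best model, or mean *training* AUC < 0.70 (0.70 exactly passes); mean test AUC is the logged alternative | — |
| projection | mean logistic suitability over the non-masked points of a 10×10 city grid; present iff strictly above the species threshold; > 50% masked points → missing, absent | — |
| contribution | permutation importance: mean training-AUC drop over 10 shuffles per variable, floored at 0, normalized to 100 (all-zero → uniform) | seed-deterministic |

Turnover classifies each species × city cell of each future scenario
against the historic baseline (gained / lost / unaffected-present /
unaffected-absent); per species, new / extirpated / unchanged city counts
and a full-extirpation flag (held ≥ 1 city historically, none in the
future); taxon roll-up is the arithmetic mean of member species' net city
change. Two identities are asserted on every run: per city net = gained −
lost = future − historic richness, and city-wise and species-wise
transition totals cross-tabulate exactly.

The statistics layer fits log-link negative-binomial GLMs (dispersion by
maximum likelihood, via statsmodels) for gains and losses on scenario,
historic richness (plus interaction), and historic MAT/MAP as continuous
covariates, reporting per-term likelihood-ratio χ² against the nested model
with the term removed; a quasi-Poisson fallback (Poisson GLM with
Pearson-estimated scale, scaled LR) is used with a warning if the NB
likelihood does not converge. City population is compared to per-city mean
gains and losses with a Pearson correlation.

## Synthetic world

The generator exists so that every stage is testable against known truth.

- **Climate**: each variable is Gaussian-smoothed white noise (kernel width
  6 cells), standardized and made exactly mutually uncorrelated over land
  by Gram-Schmidt; MAT adds a monotone north-south gradient (warm south,
  ~22 °C to ~4 °C) and MAP is kept positive (~900 ± 280 mm). A contiguous
  coastal margin (8% of the lattice) is masked as ocean. Lattice: planar km
  cells (default 4.6 km), half-open membership, origin at the lower-left
  corner.
- **Collinear pairs**: the requested number of trailing variables are
  noisy copies of leading ones at |r| ≈ 0.95. Their deviation field is
  spatially smooth (real inter-variable anomalies are structured, not
  white) and their future equals the transformed source plus the same
  deviation, so pairs stay correlated under warming as real bioclim
  variables do.
- **Scenarios**: additive warming for MAT (+1.5/+3.5/+5.5 °C for
  SSP1-2.6/3-7.0/5-8.5), multiplicative precipitation factors
  (1.03/1.07/1.12) for MAP, and a fixed coupling (0.4·ΔT per SD-scale) for
  generic variables so niches on any axis are exposed to change.
- **Species**: Gaussian response on 1–3 variables, suitability
  max_prob·Π exp(−(v−opt)²/2b²), optima inside the 15–85% quantiles,
  breadths 4–10% of the variable's land range. The breadth default keeps
  niches narrow relative to the modelled domain — the continental-scale
  regime in which presence-background models are discriminative, so that
  most virtual species are modellable and a minority is gated out rather
  than the reverse.
- **Sampling**: cells drawn ∝ true suitability × accessibility bias (road
  bands every 12 cells at 5×, plus Gaussian urban hotspots at city
  centroids, amplitude 15, σ = 12 km — community-science archives are
  dominated by urban records), jittered within the cell, dated inside the
  recency window. Contamination appended at stated fractions: exact
  duplicates, ocean points, stale dates.
- **Truth occupancy**: a species truly occupies a city iff its mean true
  suitability over the 100 grid points exceeds its own land-mean historic
  suitability. For sampling ∝ suitability against a uniform background,
  the land mean is where presence density crosses background density — the
  operating point the fitted max-sens+spec threshold estimates — so the
  oracle judges the pipeline on the decision rule it implements. A fixed
  cutoff can be passed instead.

**What passing the recovery tests does and does not show.** The virtual
world has exactly Gaussian niches on the model's own covariates, stationary
bias, no dispersal limits, no biotic interactions, no observation error in
coordinates, and future climates that are deterministic transforms of the
historic field. Recovery under these conditions demonstrates the pipeline's
statistical machinery is correct and calibrated; it does not demonstrate
that real projections are accurate, which additionally depends on niche
truncation, non-equilibrium occupancy, dispersal and land cover — a
climate-only projection shares those limits by construction.

## Problem sizes

Desk-scale study conditions used by the shipped demos and tests: 60×60 to
80×80 lattices (≈ 275–370 km square), 8–20 virtual species, 150–300
occurrence records per species, 2,000 background points, 8 hinge knots, 3–4
cities. A 20-species end-to-end recovery run completes in well under a
minute on one CPU; library defaults (10,000 background points, 20 knots)
remain the tool-standard values for real-scale use.

## Numerical choices and degenerate inputs

- Ties in thinning cells and fold fallbacks are broken by seeded draws;
  every seed used by a pipeline run derives from the run seed and the
  species' rank in the sorted pool, so per-species work is
  order-independent and parallel execution is byte-identical to serial.
- Constant (zero-variance) climate variables are dropped with an explicit
  audit reason before correlation pruning; constant expanded features are
  excluded from the fit.
- Empty-E Boyce windows are skipped; fewer than 3 retained windows is
  treated as an undefined index and fails the species' gate; a flat P/E
  profile scores 0 (indistinguishable from random).
- A city grid with more than half its points masked yields missing
  suitability and an absent call, with the cause visible in the matrix.
- Pipeline stage failures quarantine the species with a reason and the run
  continues; rerunning with `resume: true` recomputes only species without
  a serialized model and reproduces a fresh run byte-for-byte.

## Known limitations

- The ensemble-averaging entry point expects member stacks already on a
  common lattice; no regridding is provided.
- The quasi-Poisson fallback reports scaled-LR χ² which is approximate;
  it exists to keep degenerate demo tables from aborting a run.
- Threshold features make suitability piecewise-constant; with few knots
  the sens=spec threshold can sit on a plateau — ties resolve to the
  smallest candidate by rule.
- The spatial-block CV is the quadrant variant only; checkerboard or
  buffered leave-one-out designs are out of scope.
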