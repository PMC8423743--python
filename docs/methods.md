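# Methods

## Model

The prediction for county-year sample *i* is

ŷ_i = β₀ + Σ_j β_j X̃_{ij} + Σ_m b_m Z_{im},  Z_{im} = K_{k(m)}(X̃_{i,a(m)}, X̃_{i,b(m)})

on min-max normalized features X̃. Each interaction term m is a pair of
catalogue variables (a self-interaction when they coincide) with exactly one
kernel; the model is linear in its coefficients, so the final fit is
ordinary least squares and every prediction decomposes exactly into
weather + soil + management + interaction contributions plus the intercept.

### Kernel registry

Six bounded bivariate kernels on [0,1]², chosen to span the qualitative
interaction shapes an agronomist would posit:

| kernel | K(x,y) | range | shape |
|---|---|---|---|
| product | x·y | [0,1] | synergy; quadratic as self-interaction |
| minimum | min(x,y) | [0,1] | limiting factor (Liebig-type) |
| maximum | max(x,y) | [0,1] | either-sufficient |
| squared_mean | ((x+y)/2)² | [0,1] | convex joint level |
| abs_diff | \|x−y\| | [0,1] | imbalance / antagonism |
| saturating_product | 1−(1−x)(1−y) | [0,1] | diminishing-returns synergy |

abs_diff is not self-admissible (identically zero on the diagonal). The
registry is user-extensible, so an alternative kernel set can be dropped in
without touching the search.

Note an identifiability fact that shapes the search: given the two parent
main effects and an intercept, saturating_product spans exactly the same
model space as product (1−(1−x)(1−y) = x+y−xy), and minimum/maximum differ
from each other only through |x−y|. Score ties between such candidates are
therefore genuine, and are resolved deterministically (below).

## Data model and pre-processing

* Panel CSV: `county_id,year[,yield],<vars…>` with `W_`/`S_`/`M_` prefixes,
  `_wk<13..52>` weekly suffixes and `_d<label>` soil-depth suffixes. Yield
  is in t/ha.
* Sub-county grid cells aggregate by the arithmetic mean for soil and the
  median for weather (robust to isolated bad cells); management is already
  county-level.
* Derived features: weekly growing degree days (daily
  GDD = max(0, (min(Tmax,cap)+max(Tmin,base))/2 − base), base 10 °C / cap
  30 °C corn defaults, × 7 days per week), rainy-day counts (precipitation
  > 1 mm) and heat units (Tmax > 30 °C). The panel stores weekly summaries,
  so the weekly counts are the indicator approximation 7·1[weekly value >
  threshold]; exact daily-resolution counters are exposed for use upstream
  of the panel. A per-county yield-trend covariate is the least-squares
  line of historical yield against year, fit on strictly prior years only
  and evaluated at the row's year — using only prior years prevents a test
  year from leaking into its own covariate.
* Normalization maps each variable to [0,1] by the min/max of designated
  fit rows (training rows only wherever a fold is involved). Values outside
  the fit range map outside [0,1] — deliberately unclipped so extrapolation
  is visible rather than silently saturated. Constant columns map to 0 and
  are kept, so catalogue indices stay stable; selection never picks them.

## Robustness score and folds

The robustness score of a candidate model is its mean validation error
(RRMSE by default, i.e. 100·RMSE/mean observed yield of the validation set;
RMSE/MAE are config-switchable) over blocked folds:

* temporal axis: distinct years split into contiguous blocks; each fold
  validates one block and trains on all strictly earlier years, so training
  years always precede validation years. The earliest block only ever
  trains (a fold with nothing earlier to train on would be empty), so k
  blocks give k−1 folds.
* spatial axis: leave-one-group-out over user-supplied county group labels
  (e.g. state).

Temporal and spatial folds are pooled with equal weight. Each fold re-fits
both the normalization and the OLS coefficients on its training rows only;
validation rows never influence a fit (asserted by an instrumented test
that corrupts validation rows and checks bit-identical coefficients).

## Selection procedure

1. **Elastic-net pre-screen, per category.** sklearn's ElasticNetCV
   (mixing ratios {0.2, 0.5, 0.8} × a 30-point penalty path, seeded
   shuffled 10-fold CV) on each category's variables; nonzero coefficients
   at the CV optimum are kept, truncated to a per-category cap
   (defaults 25 weather / 10 soil / 5 management) by descending
   |coefficient|. Categories are screened separately so dense weather
   blocks cannot crowd out soil or management.
2. **Main-effect stepwise.** Greedy forward selection over the pre-screened
   shortlist (add the candidate with the largest robustness improvement
   while the improvement ≥ tol), then backward elimination (drop the
   element whose removal most improves, or least degrades within tol, the
   score).
3. **Interaction cycles.** Repeat until a full cycle changes nothing or
   `max_cycles` (default 4) is reached:
   a. *Residual screen.* Candidate terms (ordered pairs × admissible
      kernels, symmetric mirrors deduplicated, lazily enumerated) are
      ranked by **partial** correlation with the training residuals: each
      candidate column is first projected onto the orthogonal complement
      of the current design. Raw correlation would systematically prefer
      kernels that embed main-effect content (min, max, saturating
      product) over the genuinely novel direction; the projection makes
      the ranking measure only what the candidate adds. Candidates
      collinear with the current design are dropped. The top 25 survive.
   b. *Forward stepwise* over the shortlist (≤ 8 additions per cycle),
      then *backward elimination* over the whole selection.
   c. *Strong heredity.* Parents of selected terms are added as features
      and protected from backward elimination while their term remains.
      Per-fold normalization is an affine map, so a product term's span is
      invariant to renormalization only when its parent main effects are
      present; without heredity, a score-neutral parent removal silently
      changes what the term means across folds and leaves residual signal
      that attracts spurious correlated terms.

### Numerical choices

* Tolerances `tol_forward = tol_backward = 0.15` RRMSE points. Calibrated
  in a design pilot as ≈3× the chance improvement of the best
  noise candidate in a 25-term shortlist at the reference scenario's fold
  sizes (n ≈ 1000, 7 folds); genuine interactions at the scenario's effect
  sizes improve the score by ≈1 point. Metric-unit tolerances scale with
  the metric chosen.
* Tie margin 1e-6: candidate scores within it are ties, resolved by
  canonical order (catalogue index of var_a, then var_b, then kernel
  registry order). Needed because equivalent-span kernels (see above)
  differ only by least-squares float noise.
* Rank-deficient designs are fit by numpy's minimum-norm least squares
  with a warning; a hard error is raised only when a fold's training rows
  cannot identify the coefficient count.
* Everything is deterministic given panel + seed + config; the elastic-net
  CV shuffle is the only seeded randomness inside selection.

## Yield dissection and partial dependence

Contributions are read directly off the linear form: weather = Σ_{j∈W} β_j
X̃_ij, likewise soil and management; interaction = Σ_m b_m Z_im. Their sum
plus the intercept equals the prediction exactly (tested to 1e−10).
Partial dependence of one or two variables clamps them to grid points on
the normalized scale and averages predictions over the panel rows; exports
carry the back-transformed original units.

## In-season forecasting

One pre-season fit is used all season (no weekly re-training). At week w,
each historical donor year contributes one scenario: weekly columns ≤ w
from the target season, later weekly columns from the donor, static columns
from the target. Cumulative management progress curves are spliced
monotonically by default — the donor value floored at the last observed
target value — with a raw-copy option. Scenario predictions are summarized
by the median and first/third quartiles using linear interpolation between
order statistics (numpy's default percentile rule). At week 52 all
scenarios equal the observed row, so the band collapses onto the point
prediction exactly.

## Synthetic generator

The generator emulates the structure the method assumes, with full ground
truth for recovery scoring. Reference conditions (the package defaults):

* 50 counties × 20 years (n = 1000).
* Weather: four stems (Tmax, Tmin, Prcp ≥ 0, Srad) over weeks 20–29, each
  an independent AR(1) (ρ 0.3–0.5) around a seasonal sinusoid — 40
  variables.
* Soil: five properties at two depths, drawn once per county — 10
  variables.
* Management: logistic planting progress at weeks 20/22 (county-year
  midpoint ~N(21, 1.2²)), harvest progress at week 44, planted acreage,
  and a per-county linear yield-trend covariate — 5 variables.
* Yield: β₀ = 6 t/ha plus six additive effects (e.g. −1.2 for Tmax week
  24, +2.0 for topsoil organic matter, +3.0 for the trend covariate, on
  the normalized scale) plus two product interactions —
  Prcp wk24 × Tmax wk26 (b = +10) and Srad wk27 × planted wk22 (b = −8) —
  plus N(0, 0.45²) noise. The interaction coefficients give per-county
  contributions of a few t/ha, the magnitude county-level E×M interaction
  effects reach, and are far above the |b|/σ ≥ 3 identifiability floor:
  at that floor alone, the beyond-main-effects part of a product of
  min-max-normalized Gaussian features would sit below the noise, so the
  floor is a necessary, not sufficient, condition for detection.

What the generator does **not** emulate: spatial correlation between
neighboring counties, year-to-year weather persistence, heteroscedastic or
skewed yield noise, measurement error in progress reports, and any real
crop physiology. Passing recovery tests therefore shows the search finds
planted structure under the model's own assumptions at realistic effect
sizes — not that it recovers true agronomy from real data.

## Problem sizes used by the test suite

Unit tests run on panels of 60–1000 rows; the recovery check uses 100
seeded replicates of the reference scenario (full pipeline per replicate);
the greedy-vs-exhaustive check uses 20 instances of 8 orthogonalized
candidates; the acceptance script uses 20 reference replicates plus one
temporal-holdout evaluation. These sizes exercise every code path while a
full run of suite + script stays in the minutes range on one CPU.

## Known limitations

* The stepwise search is greedy: it finds high-quality robust sets but
  does not guarantee a globally optimal subset.
* Only self- and two-way interactions are represented; three-way and
  higher structure is out of scope.
* The kernel set is fixed per run; kernel *choice* is part of the search,
  but kernel *shape* is not learned.
* RRMSE uses the mean observed yield of the evaluation set as the
  denominator; with near-zero mean response the metric is undefined
  (guarded by an explicit error).
* Equivalent-span kernels are distinguished by convention (canonical
  order), not by data — on data truly generated by one of them, the
  reported kernel label for a tied pair is the canonical one.
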