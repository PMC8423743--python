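# interactreg

Interaction regression for county-level crop yield prediction.

County-year crop yields are driven by weather (W), soil (S), management (M)
and — crucially — their interactions: late planting hurts more in a
low-radiation summer, heat stress depends on how much rain fell, and so on.
Black-box learners can exploit such structure but cannot say *which*
interactions matter; plain linear models are explainable but purely additive.
`interactreg` sits in between. It is aimed at quantitative agronomists and
forecasters working with county-year panels (weekly weather, soil profiles by
depth, planting/harvest progress) who want accurate yield predictions *and*
an explicit, auditable list of environment×management interactions.

## The model

For sample *i* (one county in one year) with normalized explanatory
variables X, the prediction is a linear model augmented with kernel-encoded
interaction columns:

    ŷ_i = β₀ + Σ_{j∈𝒫} β_j X_{i,j} + Σ_{m∈ℳ} b_m Z_{i,m}

where each interaction m pairs two variables (a self-interaction when they
coincide) with exactly one kernel from a registry 𝒦:

    Z_{i,m} = Σ_{k∈𝒦} δ_{m,k} K_k(X_{i,a(m)}, X_{i,b(m)}),   δ_{m,k} ∈ {0,1}

The default registry holds six bounded kernels on the unit square — product
x·y (a quadratic effect when a = b), minimum, maximum, squared mean
((x+y)/2)², absolute difference |x−y|, and saturating product 1−(1−x)(1−y) —
spanning synergy, limiting-factor and antagonism shapes. With p variables
the candidate space is p² ordered pairs (self-pairs included); at the scale
of a real county panel (613 variables) that is 375,769 candidate pairs,
so terms are found by search, not enumeration:

1. **Elastic-net pre-screen** shortlists variables within each category
   (weather / soil / management) at a CV-tuned penalty.
2. **Robust stepwise search**: candidates are added and pruned by their
   *robustness score* — mean validation error (RRMSE by default) over
   blocked folds spanning different year ranges (temporal axis) and
   different county groups (spatial axis) — so a term survives only if it
   predicts well across years *and* places. An outer loop alternates
   between screening new kernel candidates against the current model's
   residuals (partial correlation) and cross-validating them, until a full
   cycle changes nothing.
3. **Final OLS fit** of the selected features and terms, after which every
   prediction dissects exactly into weather + soil + management +
   interaction contributions plus the intercept.

A season module turns the fitted model into weekly in-season forecasts:
weather/management observed through week w is spliced with each historical
year's completion, every scenario is predicted, and the median with a
first/third-quartile band is reported; by week 52 the band collapses onto
the point prediction.

A synthetic panel generator (`interactreg.synth`) emulates the panel's
statistical structure — AR(1) weekly weather around a seasonal mean, static
per-county soil, logistic progress curves, planted additive and kernel
effects plus Gaussian noise — with full ground truth, so selection and
fitting are testable without any data download.

## Worked example

```python
import interactreg as ir
from interactreg.panel import combine_folds

# reference synthetic scenario: 50 counties x 20 years, 55 variables,
# two planted product interactions
panel, truth = ir.generate_panel(ir.reference_config(seed=1))

temporal = ir.make_folds(panel, "temporal_blocks", n_blocks=4)
groups = {c: ("A" if int(c[-3:]) < 25 else "B") for c, _ in panel.rows}
folds = combine_folds(temporal, ir.make_folds(panel, "spatial_holdout", groups=groups))

result = ir.search_robust_interactions(panel, folds, config=ir.SearchConfig(seed=1))
for t in result.terms:
    print("interaction:", t.var_a, "x", t.var_b, "kernel =", t.kernel_id)

model = ir.fit_model(panel, result.features, result.terms)
metrics = ir.evaluate(panel.y, ir.predict(model, panel), ["RMSE", "RRMSE", "R2"])
print({k: round(v, 3) for k, v in metrics.items()})
```

prints

```
interaction: W_srad_wk27 x M_planted_wk22 kernel = product
interaction: W_tmax_wk26 x W_prcp_wk24 kernel = product
{'RMSE': 0.493, 'RRMSE': 6.665, 'R2': 0.925}
```

Both planted interactions (solar radiation in week 27 × planting progress in
week 22; maximum temperature in week 26 × precipitation in week 24) are
recovered with the correct product kernel, and the fit explains the panel
with an RMSE of ~0.49 t/ha (6.7% of mean yield).
`ir.decompose_contributions(model, panel)` then splits every predicted yield
into the four contribution channels, and `ir.partial_dependence` exports the
marginal effect of any one or two variables.

The same pipeline is scriptable from a shell:

```sh
interactreg simulate --config sim.yaml --out runs/sim
interactreg fit      --config fit.yaml --out runs/fit
interactreg evaluate --config eval.yaml --out runs/eval
```

Each command writes its artifacts (CSV/JSON) plus a config echo so reruns
with the same config and seed are byte-identical.

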