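# washmap

Model-based geostatistics for mapping access to drinking-water and
sanitation facilities across low- and middle-income settings: gridded
estimates of four mutually exclusive, collectively exhaustive facility
categories (safest to least safe), with posterior uncertainty, national
calibration, admin-unit reporting, burden counterfactuals, and
geographical-inequality metrics. It is aimed at quantitative epidemiologists
and small-area-estimation practitioners who need the full pipeline — from
cluster-survey counts to calibrated admin-2 tables — as tested, reusable
code, exercised end-to-end on a reproducible synthetic world.

## The model

Access is an ordinal four-category outcome handled by a continuation-ratio
decomposition: three binomial models for `p1`, `q2 = P(cat 2 | not 1)` and
`q3 = P(cat 3 | not 1, 2)`, recombined as

    p2 = (1 − p1) q2,   p3 = (1 − p1)(1 − q2) q3,   p4 = (1 − p1)(1 − q2)(1 − q3)

so the four categories always sum to one — in every posterior draw. Each
conditional model is a stacked ensemble feeding a spatial binomial
mixed model:

1. **Child learners** (penalised-spline GAM, boosted regression trees,
   lasso logistic regression) are fitted with five-fold out-of-sample
   stacking; their predictions become covariates.
2. **Parent model**: `logit p(s,t) = x(s,t)'β + u(s,t)` with `u` a Gaussian
   field, Matérn ν=3/2 in space × AR1 in time, fitted per country by an
   exact Laplace/Newton scheme on the grid; 250 joint posterior draws of the
   surface carry all downstream uncertainty (95% intervals are the
   2.5th–97.5th draw percentiles).
3. **Calibration**: gridded draws are raked by a uniform logit shift, per
   draw and year, so national population-weighted aggregates match a
   national spline trend model — in continuation-ratio space, preserving
   the sum-to-one structure exactly.
4. **Reporting**: population-weighted admin aggregation; mean annual change
   over the 18-year span 2000–2017; counts without access; dominant-type
   (>60%) and high-access (≥80%) classification with transition typology;
   comparative-risk-assessment attributable and averted deaths
   (PAF = (ΣP·RR − 1)/ΣP·RR); population-weighted Gini and disparity
   metrics across admin-2 units.

A seeded synthetic-world generator (gridded population, covariates, nested
admin units, spatiotemporal truth surfaces, cluster/areal/national survey
simulators) provides data with the statistical structure the analysis
assumes. See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

```python
from washmap.pipeline import PipelineConfig, run

cfg = PipelineConfig(seed=1)          # 16x16 grid, 4 countries, 2000-2017
run(cfg, "out")                        # world -> fit -> rake -> ... -> validate
```

This writes, among others, `out/units.csv` (per unit-year-indicator access
with uncertainty), `out/inequality.csv`, `out/burden.csv` and
`out/cv_report.csv`. Inspecting the run:

```python
import pandas as pd
units = pd.read_csv("out/units.csv")
row = units[(units.unit_id == "C0A0S0") & (units.indicator == "cat1")
            & (units.year == 2017)].iloc[0]
print(f"{row['mean']:.3f} ({row.lower:.3f}-{row.upper:.3f})")
cv = pd.read_csv("out/cv_report.csv").iloc[0]
print(f"rmse {cv.rmse:.3f}  bias {cv.bias:.4f}  coverage95 {cv.coverage95:.3f}")
```

prints (seed 1):

```
0.691 (0.598-0.764)
rmse 0.105  bias 0.0019  coverage95 0.947
```

i.e. an estimated 69.1% (95% UI 59.8–76.4) of admin-2 unit `C0A0S0`'s
population in the safest facility category in 2017, and five-fold
out-of-sample metrics showing a well-calibrated fit (95% predictive
intervals cover 94.7% of held-out clusters). Country-level aggregates are
calibrated to the national trend model, so their draws collapse onto the
national series by construction; subnational units retain full posterior
spread. The same pipeline is available from the shell:

```sh
washmap run-all --seed 1 --out out        # or: simulate / fit / rake / ...
```

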