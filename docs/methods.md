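# Methods

`washmap` implements a model-based geostatistics pipeline for mapping access
to drinking-water and sanitation facilities: four mutually exclusive,
collectively exhaustive facility categories estimated on a grid over a study
period, with full posterior uncertainty, national calibration, admin-unit
reporting, burden counterfactuals, and geographical-inequality metrics. This
note records the statistical model, the choices that were genuinely open,
the synthetic data-generating process, and the package's known limits.

## The ordinal continuation-ratio model

Facility access is a four-category ordinal outcome ordered from safest to
least safe (water: piped, other improved, unimproved, surface water;
sanitation: sewer/septic, other improved, unimproved, open defecation).
Rather than modelling the four categories jointly, the pipeline fits three
*conditional* binomial models:

1. `p1` — probability of the safest category;
2. `q2` — probability of the second category, given not the first;
3. `q3` — probability of the third, given neither of the first two.

Recombination `p2 = (1−p1)q2`, `p3 = (1−p1)(1−q2)q3`,
`p4 = (1−p1)(1−q2)(1−q3)` guarantees non-negative category probabilities
summing to one — applied per posterior draw, so the uncertainty inherits
the mutually exclusive structure. The safest-first conditioning order is part
of the public contract; the 0/0 conditional in the inverse map is defined as
0 and unit-tested. Survey records contribute binomial observations
`(n1, N)`, `(n2, N−n1)`, `(n3, N−n1−n2)`; levels with a zero denominator
are dropped — such records carry no information about those models.

## Stacked ensemble

Each conditional dataset is first fit by three child learners — a penalised
B-spline binomial GAM (additive smooth surface over grid row/column plus
linear covariate and year terms), gradient-boosted trees (depth 3, learning
rate 0.1, up to 500 rounds with early stopping on an internal split), and
L1-penalised logistic regression on standardised features. Five-fold
stacking by cluster produces strictly out-of-sample child predictions per
observation; full-data refits give the per-cell/year child rasters. Child
probabilities are clipped to `[1e-4, 1−1e-4]` and enter the parent model on
the logit scale with unconstrained coefficients (a declared choice; a
sum-to-one constraint is a reasonable alternative we did not adopt).

Data-driven hyperparameters (the GAM penalty and the lasso penalty) are
selected once per stacking call by a small k-fold deviance grid on the full
data and then frozen for the fold refits. We use cross-validated deviance
rather than analytic GCV for the GAM penalty because it is the same
machinery as the lasso selection, is robust at a few hundred observations,
and is cheap once frozen. The infinite-penalty limit of the lasso is honored
exactly: if all coefficients shrink to zero the child returns the pooled
empirical rate (the analytic limit with an unpenalised intercept).

## Spatial parent model

For each country and conditional level the parent model is

    logit p(s, t) = x(s, t)'β + u(s, t)

with `x` the (logit) stacked child features plus an intercept and `u` a
zero-mean Gaussian field with separable covariance: Matérn ν=3/2 in space
(kernel selectable; exponential also available) times an AR1 correlation
over years. Countries are fitted independently; there is no cross-border
pooling.

Inference is an exact Gaussian-field formulation on the grid, not an
SPDE/mesh approximation: the latent field values at the observed
(cell, year) sites plus β (Gaussian prior, sd 10) are found by penalised
Newton iteration (a Laplace approximation), and the three covariance
hyperparameters (log spatial sd, log range, atanh AR coefficient) maximise
the Laplace marginal likelihood plus weak Gaussian priors centred at the
configured initial values (defaults: sd 0.5, range 6 cells, AR 0.9; prior
scales 1.0/0.75/0.5). Optimisation is Nelder-Mead with a capped function
budget (default 60 evaluations; the pipeline's accuracy is insensitive to
this once past ~30). Non-convergence of the inner Newton loop raises an
explicit error with the gradient norm.

Joint surface draws (default 250, the number used for all reported
uncertainty intervals) combine a draw of (β, f_sites) from the Laplace
Gaussian with conditional simulation of the field at every prediction
cell/year. Unconditional field draws exploit the Kronecker structure of the
separable covariance (`L_s G L_t'`), then are corrected by kriging against
the drawn site values, so each draw carries coherent spatial and temporal
correlation. Fitted probabilities are clipped at `[1e-6, 1−1e-6]` on the
logit scale. A random-walk Metropolis backend preconditioned by the Laplace
curvature is selectable; the draw-cube contract is identical.

## National calibration (raking)

A penalised-spline binomial trend on year (linear logit fallback below five
year points; below three the country is excluded) is fitted to nationally
representative series per country and conditional level. Each draw cube is
then raked: for every draw and year a single additive logit shift δ is found
by Brent root-finding (bracket ±20, tolerance 1e-8) so the national
population-weighted aggregate matches the national series. Raking operates
in continuation-ratio space, and levels 2 and 3 use the population *at risk*
under the already-raked upstream levels as weights. With those weights the
recombined category aggregates hit all four national category targets
exactly; with raw population weights they would not, because the covariance
between `(1−p1)` and `q2` across cells breaks the factorisation. We rake
every draw against the national mean series (not draw-matched national
draws) — a simpler convention, stated openly. Its visible consequence is
that country-level aggregates have (near-)zero posterior spread after
calibration: national uncertainty is deferred to the national model, while
subnational units retain full spread.

## Aggregation, burden, inequality

All summaries are computed on draws, never on summaries: a function of the
surface is evaluated per draw, then the mean and 2.5th/97.5th percentiles
are reported. Admin aggregation is population-weighted and linear, so nested
aggregation is consistent at machine precision. The mean annual change
divides the 2000–2017 change by 18 (the span consistent with all three
published worked examples). Dominant facility classes use a strict >60%
rule on grouped shares (improved = categories 1+2, unimproved = 3, none =
4); high access is ≥80%. Transition typology: none→improved is a
substantial upgrade; none→unimproved and unimproved→improved are
incremental; everything else "other".

The comparative risk assessment combines exposure distributions (facility
categories crossed with household water-treatment prevalence under
within-unit independence, for the water domain) with a user-supplied
relative-risk table (reference category RR=1, all RR≥1). PAF = (RW−1)/RW
with RW = ΣP·RR; attributable deaths are D·PAF; counterfactual deaths under
year-2000 exposure are D·RW_2000/RW_2017, holding the cause-deleted
envelope fixed, so averted = D(RW_2000/RW_2017 − 1) and worsening access
yields negative (caused) deaths. The shipped risk-ratio table and the
mortality/treatment inputs the pipeline generates are synthetic
placeholders, labelled as such — the package estimates neither risks nor
mortality.

Geographical inequality uses the population-weighted pairwise Gini across
admin2 units (weight-rescaling invariant, Pigou–Dalton consistent, checked
against the Lorenz-curve formulation), plus range/gap/ratio disparity
metrics; the ratio is flagged undefined when the minimum access is zero.
An unweighted Gini is available by omitting the weights.

## The synthetic world

The generator is the package's stand-in for restricted multi-country survey
microdata; the real study's data-generating process is unknown, so every
choice here is a declared simulator convention, not a reproduction:

* Geometry is an abstract planar grid (row-major, origin top-left, unit
  cells); countries tile the grid into contiguous rectangles subdivided into
  rectangular admin1/admin2 units. Configurations in which an admin2 unit
  would own zero cells are rejected.
* Population is a log-Gaussian random field scaled exactly to the configured
  total; covariates are independent stationary Matérn ν=3/2 fields, constant
  over time.
* The three true conditional logit surfaces are linear covariate effects
  plus a separable spatiotemporal Gaussian field (Matérn × AR1) plus a
  country-specific linear year trend; fields are generated by dense Cholesky
  factors, exact at desk scale.
* Surveys: point clusters sample cells proportional to population and draw
  multinomial household counts from the cell/year truth; areal records draw
  from the population-weighted unit mean; national series are one large
  areal record per year (default 4 000 households).

Default problem sizes are the package's desk-scale study conditions: a
16×16 grid, 4 countries × 2 admin1 × 2 admin2 (16 reporting units), years
2000–2017, 7 covariates, 20 clusters of 25 households per country-year, and
250 posterior draws. These sizes make a full pipeline run take about a
minute on one CPU while leaving every statistical mechanism (spatial
correlation, temporal trends, stacking, calibration) active. What passing
tests on this world show is that the machinery is correct and calibrated
under its own assumptions; they cannot show robustness to survey bias,
design weights, misclassification, non-stationarity, or real covariate
quality, none of which the generator emulates.

## Numerical conventions and reproducibility

Covariance matrices carry a 1e-8 jitter; AR1 factors 1e-10. Largest-
remainder allocation breaks ties toward the lower cell index; areal-to-point
category apportionment uses controlled rounding (floor + greedy remainder
assignment respecting both margins) so every total is conserved exactly.
Every stochastic operation derives its generator from the master seed plus a
stable string tag (crc32), so stages can be rerun independently and the full
pipeline is bitwise reproducible — including LightGBM (deterministic mode,
single thread) and the CSV float formatting (`%.10g`). Stages communicate
only through serialized artifacts (CSV, headered text rasters, draw-cube
arrays with JSON sidecars) and can run in separate processes.

## Known limitations

* The Laplace approximation understates skewness for extreme prevalences;
  the MCMC backend exists for checking but is not the default.
* Hyperparameters are point-estimated (empirical Bayes); their uncertainty
  is not propagated into the draw cubes.
* Cross-validation predictive intervals include binomial sampling noise
  (posterior-predictive coverage); latent-probability coverage would be
  narrower and is not what the reported 95% coverage measures.
* The five-fold validation stage defaults to the first conditional level and
  one country to keep the default run fast; the scope is configurable.
* No geodesy: distances are grid distances; the generator does not emulate
  projection effects, coastlines, or real admin geometries.
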