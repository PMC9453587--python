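# Methods

This note records the model, the numerical choices, and the design
decisions behind `pathimpact`, in the order the pipeline runs.

## Data model

The unit of analysis is the census tract (population ~1,200–8,000), observed
yearly. A `CityPanel` holds one row per (tract, year) and one column per
observed variable; a catalog tags every variable with its source category
(ACS demographics; CDC 500 Cities health outcomes, behaviors, prevention,
status; municipal path mileage; path-use counts). Tract IDs are opaque
11-digit FIPS strings — any GIS joining is assumed done upstream, and no
geometry is stored. Mileage is stored in miles; the `miles_to_km` helper
uses the exact international factor 1.609344 and exists for reporting only.

Missing data policy: a variable missing in more than 20% of tract-years is
dropped with a warning; remaining missing cells are mean-imputed within
year, so secular trends are not smeared across the panel. Complete-case
analysis was rejected because the exploratory half of a small city leaves
too few rows.

## Factor model

We assume the observed variables are generated by three correlated latent
factors per tract — demographics and background characteristics (DBC),
adverse-health burden (health), and bicycling/pedestrian habits (BPH) —
with linear loadings and Gaussian unique noise, i.e. every variable pair is
bivariate normal. Factor scores are standardized, so they are positions in
SD units within the city.

**Split.** Tracts are partitioned at random; the larger (ceiling) half goes
to EFA so that a 77-tract, 5-year city gives 195/190 tract-year rows and a
195-tract city 490/485. The split is simple random sampling (no
stratification) and deterministic under its seed.

**Extraction and rotation.** Variables are z-standardized on the fitting
half. Extraction is maximum-likelihood (EM) factor analysis; rotation is
oblique quartimin via the gradient-projection algorithm with unit-length
rotation columns and step halving, followed by a sign convention that makes
each factor's dominant loadings positive. Oblique rotation is required
because the three substantive factors are expected to correlate (tract-level
SES–health gradients are strong). Both pieces are implemented on
numpy/scipy (extraction via scikit-learn) because no dedicated EFA/CFA
package is a dependency of this project.

**The communality filter.** The model-assessment rule — every variable must
have high communality (> 0.5) with its own factor and low (< 0.5) with all
others — is operationalised as follows. The communality of variable *i*
with factor *g* is the *mean squared sample correlation between i and the
variables assigned to g* (assignment = argmax |pattern loading|). This
reading of "the amount of variance an observed variable shares with the
other variables in a factor" is deliberately rotation-invariant: an oblique
rotation has enough freedom to tilt a factor toward a variable that in truth
straddles two factors, which makes pattern- or structure-loading versions of
the rule unreliable exactly for the variables the rule exists to catch. A
0.45/0.45 straddler shares at most ~25% variance with any factor's markers
and is discarded with a wide margin, while a 0.9-loading marker shares ~81%
with its own factor and ≤ ~35% across even when factor-correlation estimates
are inflated. On top of the invariant rule, simple structure is enforced on
the rotated pattern matrix itself (assigned |loading| > 0.5, all cross
|loadings| < 0.5), which is what the fitted model displays.

All violating variables are discarded per iteration and the model refitted;
the discarded set grows monotonically, so the loop terminates in at most
|candidate| iterations.

**Number of factors.** The smallest m in 3..`max_factors` (default 6) whose
filtered solution retains at least three variables on every factor is
accepted. Each candidate m restarts from the full variable pool, so
variables discarded under a factor count whose solution collapsed re-enter
the search automatically (this subsumes a "dissolve the factor and return
its variables once" rule with simpler control flow). If no m is admissible
— e.g. on unstructured noise — the pipeline raises a requirements-unmet
error rather than returning a degenerate model.

**Labels.** Factors are labeled by the majority category group of their
retained variables (ACS → DBC; CDC → health; mileage/use → BPH), ties and
duplicate claims broken by the larger mean |loading| of the group's
variables. The labeled model must have all three factors, the health factor
must contain at least one health-outcome prevalence, and the BPH factor
must contain the path-mileage variable; otherwise the method is not
applicable to the city.

**Confirmation.** The CFA is a congeneric simple-structure ML model: one
free loading per variable on its assigned factor, free factor correlations,
unit factor variances, fitted on the held-out half's correlation matrix by
L-BFGS-B on the ML discrepancy (ψ bounded below at 1e-3, correlations at
±0.98, EFA estimates as starting values). Fit indices are the standard
χ²-based CFI, TLI, RMSEA and the SRMR over the unique residuals; cutoffs
(CFI ≥ 0.90, TLI ≥ 0.90, RMSEA ≤ 0.08, SRMR ≤ 0.08) are configurable. The
threshold check in the CFA applies to each variable's single free loading —
cross-loadings are structurally zero in this model, so a pattern cross-check
would be vacuous and a structure cross-check is not standard CFA practice.
On confirmation the model's loadings, factor correlations, scoring weights
and standardization constants are updated to the confirmation-half
estimates.

## Scoring

Regression (Thurstone) scores: W = R⁻¹ Λ Φ applied to z-scores, then
standardized by the fitting sample's raw-score mean and SD. The method
itself never names a scoring method; regression scoring is the common
default and maximizes correlation with the latent factor. Two regimes:

* `refit_standardization=True` recomputes and stores both the variable
  z-statistics and the score standardization on the scored tract set —
  guaranteeing per-factor mean 0, SD 1 (to 1e-8) over that set, and making
  scores invariant to affine rescaling of any observed variable.
* `refit_standardization=False` applies the stored constants unchanged.
  This frozen-model contract is what the predictor relies on: adding
  hypothetical mileage to one tract rescoring only that tract, with every
  other tract's score untouched and no model refit. We deliberately do
  *not* re-standardize the whole city after a hypothetical addition — the
  query must not shift everyone else's position.

## Prediction

The query algorithm: (1) add Δ miles to the tract's mileage variable;
(2) rescore that tract under the frozen model; (3) N_DBC = other tracts
with |DBC − DBC_query| ≤ x; (4) N_BPH likewise with the post-addition BPH
score; (5) neighbors = N_DBC ∩ N_BPH, and per health-outcome variable the
improvements are `query prevalence − neighbor prevalence` with negative
values discarded. Choices worth recording:

* **Intersection, not union**, of the two threshold sets: a meaningful
  comparison tract must be similar demographically *and* in realized path
  habits; the union would let a demographically alien tract into the set.
* **Sign convention**: improvement = query − neighbor, so a positive value
  means the neighbor — similar except for its realized path habits —
  carries a lower adverse-outcome prevalence. This orientation is the one
  consistent with discarding negatives as "would degrade health outcomes".
* **Closed balls**: ties at exactly x count as neighbors.
* **Empty neighbor set** ⇒ all summaries 0 with `empty_flag` set; these are
  the tracts where added paths are unlikely to be effective interventions.
  x = 0 is accepted as a degenerate query (radius-zero balls).
* **Sweep**: grid {0.10, 0.20, …} plus the final partial increment so the
  full requested mileage is always evaluated; the reported best median is
  the maximum over the grid, encoding the assumption that more mileage is
  never detrimental. Refining the grid can therefore only raise the result.

## Synthetic cities

The generator is the package's test bed and defines the conditions every
recovery and evaluation suite runs under. Per tract, factor scores are
drawn once from N(0, Φ) and held fixed across years; each observed variable
is `mean + scale · (loading·F + ε)`, ε ~ N(0, 0.3) per tract-year;
prevalences are clipped to [0, 100].

Default world (chosen once, for realism, during initial calibration):

* 200 tracts, years 2011–2021; 12 signal variables (4 per factor) at
  loading 0.9 — four ACS demographics, four CDC outcome prevalences
  (diabetes 11 ± 2.5%, high blood pressure 32 ± 3.5%, poor physical health
  13 ± 3%, stroke 3.5 ± 1.5%), path mileage (2 ± 1.2 mi) and three use
  counts. Outcome dispersions are kept in the 1.5–3.5-point band so planted
  effects are comparable in standardized units across outcomes.
* Factor correlations Φ = (DBC,health −0.55; DBC,BPH +0.40; health,BPH
  −0.45): the method presumes one coherent system, and tract-level
  SES–health gradients of this strength are the norm in city data.
* Two 0.45/0.45 distractors in the *contrast* configuration (equal positive
  loadings on a negatively correlated factor pair), which genuinely share
  under a quarter of their variance with every factor — the kind of
  variable the communality filter exists to discard.
* An AR(1) outcome drift (SD 0.3 pp/yr, ρ 0.8) so predict-no-change is not
  trivially perfect, plus a small secular trend: tracts improve by
  0.10·DBC + 0.15·BPH pp/yr, the BPH-linked share operating only above the
  demographic gate. The gated path-linked history is what lets an OLS
  baseline learn an (ungated, linear) path–health association from the fit
  window — the behavior the evaluation is designed to expose.
* Intervention: selected tracts gain Δ ~ U(0.3, 2.0) miles in 2016
  (persisting thereafter); from 2021 on, each outcome drops by
  `max_drop · Δ/(Δ + half_sat)` — a saturating dose response with
  max_drop = 3 pp and half-saturation at 0.5 mi — if and only if the
  tract's true DBC score is ≥ −1.0. The gate in the lower tail encodes
  "paths fail only where background disadvantage is extreme" (~16% of
  tracts). Drops are recorded exactly in the exported ground truth.

What the generator does **not** emulate: spatial autocorrelation between
adjacent tracts, sampling bias in app-derived use counts, non-Gaussian
prevalence error, policy-targeted (non-random) path placement, and
variable-specific effect sizes. Passing recovery tests on this world shows
the pipeline's machinery is correct under its own assumptions — not that
real cities satisfy them.

A note on dates: installations happen in 2016 and outcomes are evaluated
five years later counted exclusively (2021). Sources that count the window
inclusively would call 2016→2020 a 5-year lapse; the package uses exclusive
arithmetic (`intervention_year + lag`) throughout.

## Evaluation

For every intervened tract the three approaches forecast each outcome at
the horizon (intervention year + 5):

* **ours** — prevalence observed at the intervention year minus the sweep's
  best median improvement at the tract's recorded mileage, clipped to
  [0, 100]. Scores are refitted and frozen at the year *before* the
  intervention, so the algorithm sees the pre-addition city.
* **no_change** — the tract's mean prevalence over the fit window
  (2011–2015 by default).
* **linreg** — OLS of the fit-window start→end outcome change on
  [1, DBC, BPH] at the frozen scores, evaluated at the tract's
  post-addition scores and rescaled by horizon / fit-window length
  (5/4 by default). The training target for "future changes" is not
  uniquely determined by the method's description; start→end change with
  linear time-rescaling is the simplest defensible choice.

MAE and RMSE are computed over tracts per (approach, outcome); their SDs
come from a seeded nonparametric bootstrap over tracts (1000 resamples by
default). With one prediction per tract, MAE and RMSE have no natural
"per-tract SD"; the bootstrap is what reconciles a mean-(SD) presentation
with MAE ≠ RMSE. The one-tailed paired t-test compares per-tract |error|
(for MAE) or error² (for RMSE) of ours vs the better-performing
alternative; p is the lower-tail probability of t at n−1 df. A
zero-variance difference vector is flagged degenerate and p saturates to
0/1 by the sign of the mean (0.5 when the approaches agree everywhere),
with no significance claimed.

## Numerical choices and degenerate inputs

* EFA extraction: EM to tolerance 1e-4, max 5000 iterations, LAPACK SVD,
  seeded; non-finite loadings raise an estimation error.
* Quartimin GPA: gradient tolerance 1e-6, max 500 iterations, 50 step
  halvings; m = 1 returns the input unrotated.
* A zero-variance variable in a fitting sample raises an estimation error;
  in scoring, a zero SD is replaced by 1 (the variable carries no
  information, and scores must stay finite).
* At least 5 tract-year rows per candidate variable are required for EFA;
  at least 2 tracts for a split; at least 3 tracts for the OLS baseline,
  which also rejects rank-deficient designs.
* Bootstrap and all simulations take explicit seeds; identical seeds give
  byte-identical JSON artifacts.

## Problem sizes

The shipped suites run the full pipeline on cities of 120–200 tracts
(recovery suites use 20 replicates of 200 tracts; evaluation suites 10–12
replicates of 150 tracts with 40 intervened each; calibration uses 2000
replicates of 31 paired observations). These sizes bracket the 77- and
195-tract cities the method targets. Cities below roughly 80 tracts leave
an exploratory half too small for stable filtering: sampling inflation of
cross-factor correlations starts discarding genuine markers.

## Known limitations

* The improvement distribution scales with the outcome dispersion inside
  the matched neighborhood: in a city where matching on DBC and BPH leaves
  outcomes widely dispersed, the median neighbor difference sets a floor on
  predicted improvements and the forecast overshoots where true effects are
  small. The method is accurate in the regime it presumes — outcomes
  strongly structured by the three factors.
* The evaluation design cannot separate the path effect from tract-level
  secular trends; all three approaches inherit this confound.
* The CFA's simple-structure constraint (no cross-loadings) is stricter
  than the EFA it confirms; models that pass the EFA filter with moderate
  cross-structure can show inflated RMSEA in confirmation.
* Factor labels depend on the catalog's category tags; miscategorized
  variables propagate to wrong labels, not to an error.
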