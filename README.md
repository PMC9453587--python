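# pathimpact

**How many percentage points will a proposed addition of bicycle/pedestrian
path mileage improve a census tract's health outcomes?**

`pathimpact` is a factor-analytic what-if tool for city planners and public
health analysts working with tract-level panel data (ACS demographics,
CDC 500 Cities / PLACES prevalence estimates, municipal path mileage and
path-use counts). It fits a city-specific latent factor model, confirms it
on held-out tracts, and answers mileage-addition queries by matching the
queried tract to its factor-score neighbors.

## The method

1. **Split.** The city's tracts are randomly halved; all years of a tract
   stay together (a 77-tract city over 2011–2015 yields 195 exploratory and
   190 confirmation tract-year rows).
2. **Iterative EFA.** On the exploratory half, a maximum-likelihood factor
   model with oblique (quartimin) rotation is fitted for the smallest
   admissible number of factors m ≥ 3. Any variable that shares ≤ 0.5 of
   its variance with its own factor's variables, shares ≥ 0.5 with another
   factor's, or breaks the 0.5 pattern simple-structure rule is discarded,
   and the model is refitted until no violations remain.
3. **Labels.** The surviving factors must include residents' demographics
   and background characteristics (**DBC**), their adverse-health burden
   (**health** — must contain a health-outcome prevalence), and their
   bicycling/pedestrian habits (**BPH** — must contain the path-mileage
   variable).
4. **CFA.** The structure is refitted on the confirmation half as a
   simple-structure ML model and accepted only if every loading still
   clears 0.5 and CFI ≥ 0.90, TLI ≥ 0.90, RMSEA ≤ 0.08, SRMR ≤ 0.08.
5. **Scores.** Regression (Thurstone) factor scores, standardized to mean
   0, SD 1 over the city — so a score is a position in SD units.
6. **Prediction.** For a query (tract, +Δ miles): add Δ to the tract's
   mileage, rescore it under the *frozen* model, collect all other tracts
   within x = 0.50 SD of its DBC score **and** of its post-addition BPH
   score, and take the nonnegative differences
   `query prevalence − neighbor prevalence` per health outcome. The
   distribution's min/mean/median/max/SD is the answer; an empty neighbor
   set flags a tract where added paths are unlikely to be effective.
7. **Sweep.** For an evaluation-style query the algorithm runs at every
   0.10-mile increment up to Δ and reports the largest median improvement
   (adding mileage is assumed never detrimental).

An evaluation harness compares this forecast at a 5-year horizon against a
predict-no-change baseline (the tract's 2011–2015 mean) and an OLS baseline
(outcome change regressed on DBC and BPH scores), using MAE and RMSE over
tracts with bootstrap SDs, and a one-tailed paired t-test on per-tract
absolute (MAE) or squared (RMSE) errors.

Because the real city extracts are not redistributable, the package ships a
first-class synthetic-city generator (`synthetic_city`) with a planted
three-factor structure, distractor variables that must fail the communality
filter, and a lagged, demographically gated, saturating intervention effect
— with exported ground truth, so every stage is testable against a known
world.

## Worked example

```python
import pathimpact as pi

cfg = pi.SyntheticConfig(n_tracts=200, seed=1)
panel, truth = pi.simulate_intervened_city(cfg, n_intervened=40)

fit_panel = panel.subset_years(range(2011, 2016))
split = pi.split_halves(panel, seed=1)
model, efa_report = pi.run_efa(fit_panel.subset_tracts(split.efa_tracts), seed=1)
model = pi.label_factors(model, panel.catalog)
cfa_report = pi.run_cfa(model, fit_panel.subset_tracts(split.cfa_tracts))

scores = pi.compute_scores(model, panel, 2015, refit_standardization=True)
tract = sorted(t for t, m in truth.added_miles.items() if m > 0)[0]
sweep = pi.sweep_increments(model, panel, scores, tract, total_miles=1.0, year=2015)
report = pi.run_evaluation(model, panel, truth, seed=1)
```

This prints (via the obvious `print` calls):

```
retained 12 of 14 variables on 3 factors; discarded: ['annual_checkup_pct', 'pct_long_commute']
CFA confirmed=True (CFI=0.998, RMSEA=0.025)
tract 51710000007: best median improvement over 10 increments:
  diabetes_pct                2.37 percentage points
  high_blood_pressure_pct     5.13 percentage points
  poor_physical_health_pct    2.74 percentage points
  stroke_pct                  3.62 percentage points
diabetes  linreg     MAE 1.92 (SD 0.21)  RMSE 2.34 (SD 0.23)
diabetes  no_change  MAE 1.99 (SD 0.25)  RMSE 2.51 (SD 0.27)
diabetes  ours       MAE 1.68 (SD 0.25)  RMSE 2.29 (SD 0.29)
```

Reading: the iterative filter discarded exactly the two planted straddling
variables; the held-out half confirmed the three-factor structure; adding
one mile of path to tract `51710000007` is predicted to lower its diabetes
prevalence by about 2.4 percentage points (the median across its matched
neighbors, maximized over 0.10-mile increments); and over the 40 intervened
tracts the neighbor-matching forecast of 2021 diabetes prevalence is more
accurate (MAE 1.68) than predicting no change (1.99) or the regression
baseline (1.92).

The same chain is available from a shell:

```bash
pathimpact run-all --seed 1 --outdir runs/demo
pathimpact sweep --model runs/demo/model.json --panel runs/demo/panel.csv \
    --catalog runs/demo/catalog.csv --tract 51710000007 --miles 1.0 \
    --year 2015 --out sweep.json
```

## Layout

| Module | Role |
| --- | --- |
| `pathimpact.city_panel` | tract-year panel model, CSV I/O, validation, EFA/CFA half split |
| `pathimpact.synthetic_city` | planted-structure generator, intervention, ground truth |
| `pathimpact.factor_pipeline` | iterative EFA, quartimin rotation, labeling, ML CFA + fit indices |
| `pathimpact.scoring` | standardized regression factor scores, frozen-model rescoring |
| `pathimpact.predictor` | neighbor-matching query and 0.10-mile increment sweep |
| `pathimpact.evaluation` | baselines, MAE/RMSE blocks, paired one-tailed t-test |
| `pathimpact.cli` | `pathimpact` command: simulate / split / fit / score / predict / sweep / evaluate / run-all |

See `docs/methods.md` for modeling assumptions, parameter choices, and
known limitations.
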