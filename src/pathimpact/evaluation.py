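"""Baselines, accuracy measures, and the paired one-tailed test.

The harness compares three ways of forecasting a tract's health-outcome
prevalence at a horizon after paths were added:

* **ours** — the neighbor-matching sweep: prevalence observed at the
  intervention year minus the best median improvement over the 0.10-mile
  increment sweep;
* **no_change** — the tract's mean prevalence over the fit window (the
  "tomorrow will be like the last five days" forecast);
* **linreg** — ordinary least squares of the fit-window prevalence change
  on the DBC and BPH factor scores, extrapolated to the horizon at the
  post-addition scores.

Accuracy is summarised per (approach, outcome) by MAE and RMSE over tracts,
with bootstrap standard deviations, and the approaches are compared by a
one-tailed paired t-test on per-tract accuracy contributions (absolute
error for MAE, squared error for RMSE): the test asks whether the mean
paired difference ours - alternative is below zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .city_panel import CityPanel
from .factor_pipeline import FactorModel
from .predictor import sweep_increments
from .scoring import FactorScores, compute_scores, score_modified_tract
from .synthetic_city import GroundTruth

APPROACHES = ("ours", "no_change", "linreg")


@dataclass(frozen=True)
class OutcomePrediction:
    """One approach's forecast for one tract and outcome."""

    tract_id: str
    outcome: str
    approach: str
    predicted_value: float  # %
    actual_value: float  # %

    @property
    def error(self) -> float:
        return self.predicted_value - self.actual_value


# -- baselines -------------------------------------------------------------


def predict_no_change(
    panel: CityPanel, fit_years: Sequence[int], tract: str, outcome: str
) -> float:
    """Mean prevalence of the tract over the fit window."""
    df = panel.data
    mask = (df["tract_id"] == tract) & df["year"].isin(list(fit_years))
    values = df.loc[mask, outcome].dropna()
    if values.empty:
        raise ValueError(
            f"no {outcome!r} data for tract {tract} in years {list(fit_years)}"
        )
    return float(values.mean())


@dataclass
class LinregBaseline:
    """OLS forecast of outcome change from DBC and BPH factor scores.

    Trained on the fit-window start-to-end change; predictions rescale the
    fitted change by ``horizon_years / fit-window length`` and evaluate it
    at the tract's post-addition scores.
    """

    model: FactorModel
    coefficients: dict[str, np.ndarray]  # outcome -> (intercept, b_DBC, b_BPH)
    fit_years: list[int]
    horizon_years: int

    @property
    def _scale(self) -> float:
        return self.horizon_years / (self.fit_years[-1] - self.fit_years[0])

    def predict(
        self,
        panel: CityPanel,
        tract_id: str,
        added_miles: float,
        anchor_year: int,
    ) -> dict[str, float]:
        """Forecast each outcome at the horizon, clipped to [0, 100]."""
        post = score_modified_tract(
            self.model, panel, tract_id, self.fit_years[-1], added_miles
        )
        design = np.array([1.0, post["DBC"], post["BPH"]])
        out = {}
        for outcome, beta in self.coefficients.items():
            anchor = panel.value(tract_id, anchor_year, outcome)
            change = float(design @ beta) * self._scale
            out[outcome] = float(np.clip(anchor + change, 0.0, 100.0))
        return out


def linreg_baseline(
    model: FactorModel,
    panel: CityPanel,
    fit_years: Sequence[int],
    horizon_years: int = 5,
    outcomes: Sequence[str] | None = None,
) -> LinregBaseline:
    """Fit the regression baseline on the fit window.

    The response is each outcome's change from the first to the last fit
    year; the design is [1, DBC score, BPH score] at the last fit year under
    the model's frozen standardization.
    """
    fit_years = sorted(int(y) for y in fit_years)
    if len(fit_years) < 2:
        raise ValueError("fit window must span at least 2 years")
    if panel.n_tracts < 3:
        raise ValueError("need at least 3 tracts to fit the regression baseline")
    if outcomes is None:
        outcomes = model.health_outcome_variables()

    scores = compute_scores(model, panel, fit_years[-1], refit_standardization=False)
    start = panel.rows_for_year(fit_years[0])
    end = panel.rows_for_year(fit_years[-1])
    tracts = [t for t in scores.tract_ids if t in start.index and t in end.index]

    X = sm.add_constant(
        scores.scores.loc[tracts, ["DBC", "BPH"]].to_numpy(dtype=float),
        has_constant="add",
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design: DBC and BPH scores are collinear")
    coefficients = {}
    for outcome in outcomes:
        y = (end.loc[tracts, outcome] - start.loc[tracts, outcome]).to_numpy(float)
        coefficients[outcome] = sm.OLS(y, X).fit().params
    return LinregBaseline(
        model=model,
        coefficients=coefficients,
        fit_years=fit_years,
        horizon_years=horizon_years,
    )


# -- measures of effectiveness --------------------------------------------


@dataclass(frozen=True)
class MoeBlock:
    """City-level MAE and RMSE with bootstrap SDs over tracts."""

    mae: float
    mae_sd: float
    rmse: float
    rmse_sd: float
    n_tracts: int


def compute_moes(
    predictions: Iterable[OutcomePrediction],
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[tuple[str, str], MoeBlock]:
    """MAE / RMSE per (approach, outcome), SDs by nonparametric bootstrap."""
    preds = list(predictions)
    if not preds:
        raise ValueError("empty prediction set")
    frame = pd.DataFrame(
        {
            "approach": [p.approach for p in preds],
            "outcome": [p.outcome for p in preds],
            "error": [p.error for p in preds],
        }
    )
    out: dict[tuple[str, str], MoeBlock] = {}
    for (approach, outcome), group in frame.groupby(["approach", "outcome"]):
        e = group["error"].to_numpy(dtype=float)
        n = e.size
        if n < 2:
            raise ValueError(
                f"need >= 2 tracts per cell, got {n} for ({approach}, {outcome})"
            )
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        boot = e[idx]
        mae_boot = np.abs(boot).mean(axis=1)
        rmse_boot = np.sqrt((boot**2).mean(axis=1))
        out[(approach, outcome)] = MoeBlock(
            mae=float(np.abs(e).mean()),
            mae_sd=float(mae_boot.std(ddof=1)),
            rmse=float(np.sqrt((e**2).mean())),
            rmse_sd=float(rmse_boot.std(ddof=1)),
            n_tracts=n,
        )
    return out


# -- paired one-tailed t-test ----------------------------------------------


@dataclass(frozen=True)
class TTestResult:
    """Lower-tailed paired t-test of ours vs an alternative."""

    t: float
    p: float
    df: int
    degenerate: bool = False


def paired_one_tailed_t(
    ours_moe_per_tract: Sequence[float], alt_moe_per_tract: Sequence[float]
) -> TTestResult:
    """Test whether the mean of d = ours - alternative is below zero.

    Per-tract contributions are absolute errors for the MAE comparison and
    squared errors for the RMSE comparison.  A zero-variance difference
    vector is flagged degenerate: p is 0 or 1 by the sign of the mean, 0.5
    when the two approaches agree everywhere (no significance claimed).
    """
    ours = np.asarray(ours_moe_per_tract, dtype=float)
    alt = np.asarray(alt_moe_per_tract, dtype=float)
    if ours.shape != alt.shape or ours.ndim != 1 or ours.size < 2:
        raise ValueError("need two equal-length vectors of >= 2 paired MOEs")
    d = ours - alt
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        mean = d.mean()
        p = 0.5 if mean == 0 else (0.0 if mean < 0 else 1.0)
        return TTestResult(t=float("nan"), p=p, df=n - 1, degenerate=True)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(stats.t.cdf(t, df=n - 1))
    return TTestResult(t=t, p=p, df=n - 1)


# -- end-to-end evaluation -------------------------------------------------


@dataclass
class EvaluationReport:
    """Per-tract forecasts, MOE blocks, and significance tests."""

    predictions: list[OutcomePrediction]
    moes: dict[tuple[str, str], MoeBlock]
    tests: dict[tuple[str, str], dict]  # (outcome, "MAE"|"RMSE") -> test row
    intervention_year: int
    horizon_year: int

    def tidy_frame(self) -> pd.DataFrame:
        """One row per (outcome, approach) mirroring a mean-(SD) MOE table."""
        rows = []
        for (approach, outcome), blk in sorted(self.moes.items()):
            rows.append(
                {
                    "outcome": outcome,
                    "approach": approach,
                    "MAE": blk.mae,
                    "MAE_sd": blk.mae_sd,
                    "RMSE": blk.rmse,
                    "RMSE_sd": blk.rmse_sd,
                    "n_tracts": blk.n_tracts,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "intervention_year": self.intervention_year,
            "horizon_year": self.horizon_year,
            "moes": {
                f"{a}/{o}": vars(blk).copy() for (a, o), blk in self.moes.items()
            },
            "tests": {f"{o}/{m}": row for (o, m), row in self.tests.items()},
            "predictions": [
                {
                    "tract_id": p.tract_id,
                    "outcome": p.outcome,
                    "approach": p.approach,
                    "predicted": p.predicted_value,
                    "actual": p.actual_value,
                }
                for p in self.predictions
            ],
        }


def run_evaluation(
    model: FactorModel,
    panel: CityPanel,
    truth: GroundTruth,
    intervention_year: int = 2016,
    horizon: int = 5,
    x: float = 0.50,
    step: float = 0.10,
    fit_years: Sequence[int] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> EvaluationReport:
    """Evaluate all three approaches on every intervened tract.

    The algorithm is run against the city's pre-addition state (the year
    before the intervention): factor scores are refitted there and frozen,
    and the sweep hypothetically adds each tract's recorded mileage.  All
    approaches are anchored at the intervention-year observation and scored
    against the outcome observed at ``intervention_year + horizon``.
    """
    if truth.added_miles is None or not truth.added_miles:
        raise ValueError("ground truth records no intervened tracts")
    baseline_year = intervention_year - 1
    horizon_year = intervention_year + horizon
    if horizon_year not in panel.years:
        raise ValueError(f"panel has no rows at horizon year {horizon_year}")
    if fit_years is None:
        fit_years = [y for y in panel.years if y <= baseline_year][-5:]
    fit_years = sorted(fit_years)

    scores = compute_scores(model, panel, baseline_year, refit_standardization=True)
    outcomes = model.health_outcome_variables()
    linreg = linreg_baseline(model, panel, fit_years, horizon, outcomes)

    predictions: list[OutcomePrediction] = []
    intervened = sorted(t for t, miles in truth.added_miles.items() if miles > 0)
    for tract in intervened:
        miles = truth.added_miles[tract]
        sweep = sweep_increments(
            model, panel, scores, tract, miles, x=x, step=step, year=baseline_year
        )
        lr_pred = linreg.predict(panel, tract, miles, anchor_year=intervention_year)
        for outcome in outcomes:
            anchor = panel.value(tract, intervention_year, outcome)
            actual = panel.value(tract, horizon_year, outcome)
            ours_val = float(np.clip(anchor - sweep.best_median[outcome], 0.0, 100.0))
            predictions.append(
                OutcomePrediction(tract, outcome, "ours", ours_val, actual)
            )
            predictions.append(
                OutcomePrediction(
                    tract,
                    outcome,
                    "no_change",
                    predict_no_change(panel, fit_years, tract, outcome),
                    actual,
                )
            )
            predictions.append(
                OutcomePrediction(tract, outcome, "linreg", lr_pred[outcome], actual)
            )

    moes = compute_moes(predictions, n_boot=n_boot, seed=seed)

    tests: dict[tuple[str, str], dict] = {}
    frame = pd.DataFrame(
        {
            "tract": [p.tract_id for p in predictions],
            "outcome": [p.outcome for p in predictions],
            "approach": [p.approach for p in predictions],
            "error": [p.error for p in predictions],
        }
    )
    for outcome in outcomes:
        sub = frame[frame["outcome"] == outcome].pivot(
            index="tract", columns="approach", values="error"
        )
        for moe_name, transform in (("MAE", np.abs), ("RMSE", np.square)):
            alts = {
                a: moes[(a, outcome)].mae if moe_name == "MAE" else moes[(a, outcome)].rmse
                for a in ("no_change", "linreg")
            }
            best_alt = min(alts, key=alts.get)
            result = paired_one_tailed_t(
                transform(sub["ours"].to_numpy(float)),
                transform(sub[best_alt].to_numpy(float)),
            )
            tests[(outcome, moe_name)] = {
                "alternative": best_alt,
                "t": result.t,
                "p": result.p,
                "df": result.df,
                "degenerate": result.degenerate,
            }

    return EvaluationReport(
        predictions=predictions,
        moes=moes,
        tests=tests,
        intervention_year=intervention_year,
        horizon_year=horizon_year,
    )
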