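"""Standardized factor scores for every tract under a fitted model.

Scores are regression (Thurstone) scores: the model's scoring weights are
applied to z-standardized observed variables and the raw scores are then
standardized to mean 0, SD 1.  Two regimes matter:

* ``refit_standardization=True`` — both the variable z-statistics and the
  score mean/SD are recomputed on the scored tract set and stored on the
  model.  This is how a whole city is scored, and it guarantees each
  factor's scores have mean 0 and SD 1 over that set.
* ``refit_standardization=False`` — the stored constants are applied
  unchanged.  This is the frozen-model contract the prediction algorithm
  relies on: rescoring one tract after a hypothetical mileage addition must
  not shift anyone else's scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .city_panel import CityPanel
from .factor_pipeline import FactorModel


@dataclass
class FactorScores:
    """Per-tract standardized factor scores for one panel year.

    ``scores`` is indexed by tract ID with one column per factor label
    (DBC / health / BPH / factor_k for unlabeled factors).
    """

    scores: pd.DataFrame
    year: int

    def of(self, tract_id: str, label: str) -> float:
        return float(self.scores.loc[tract_id, label])

    @property
    def tract_ids(self) -> list[str]:
        return list(self.scores.index)


def compute_scores(
    model: FactorModel,
    panel: CityPanel,
    year: int,
    refit_standardization: bool = False,
) -> FactorScores:
    """Score every tract of ``panel`` at ``year`` under ``model``.

    Raises a KeyError naming the first retained variable missing from the
    panel.  With ``refit_standardization`` the standardization constants are
    recomputed on this tract set and stored on the model (mutating it);
    otherwise the stored constants are applied as-is.
    """
    missing = [v for v in model.retained_vars if v not in panel.variables]
    if missing:
        raise KeyError(f"panel lacks retained variable {missing[0]!r}")
    rows = panel.rows_for_year(year)
    X = rows[model.retained_vars].to_numpy(dtype=float)

    if refit_standardization:
        var_means = X.mean(axis=0)
        var_sds = X.std(axis=0, ddof=1)
        if np.any(var_sds == 0):
            # a constant column carries no information; keep it finite
            var_sds = np.where(var_sds == 0, 1.0, var_sds)
        model.var_means = var_means
        model.var_sds = var_sds
    Z = (X - model.var_means) / model.var_sds
    raw = Z @ model.scoring_weights
    if refit_standardization:
        model.score_means = raw.mean(axis=0)
        model.score_sds = raw.std(axis=0, ddof=1)
        if np.any(model.score_sds == 0):
            model.score_sds = np.where(model.score_sds == 0, 1.0, model.score_sds)
    standardized = (raw - model.score_means) / model.score_sds

    frame = pd.DataFrame(
        standardized, index=rows.index, columns=model.label_names
    )
    return FactorScores(scores=frame, year=year)


def score_modified_tract(
    model: FactorModel,
    panel: CityPanel,
    tract_id: str,
    year: int,
    added_miles: float,
) -> dict[str, float]:
    """Score one tract after a hypothetical mileage addition, frozen model.

    Only the queried tract is rescored; the stored standardization constants
    are applied so the rest of the city's scores are untouched by
    construction.
    """
    if tract_id not in panel.tract_ids:
        raise KeyError(f"unknown tract {tract_id!r}")
    rows = panel.rows_for_year(year)
    values = rows.loc[tract_id, model.retained_vars].to_numpy(dtype=float).copy()
    mileage_var = panel.mileage_variable
    if mileage_var in model.retained_vars:
        values[model.retained_vars.index(mileage_var)] += added_miles
    z = (values - model.var_means) / model.var_sds
    raw = z @ model.scoring_weights
    standardized = (raw - model.score_means) / model.score_sds
    return dict(zip(model.label_names, standardized.tolist()))
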