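"""Shared fixtures: synthetic cities, a fitted model, and stub models.

The expensive fixtures (a simulated intervened city and its fitted,
labeled, CFA-confirmed factor model) are session-scoped; tests that mutate
a model's standardization constants work on copies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pathimpact as pi
from pathimpact.factor_pipeline import FactorModel

FIT_YEARS = range(2011, 2016)


@pytest.fixture(scope="session")
def city():
    """120-tract intervened city under the default study conditions."""
    cfg = pi.SyntheticConfig(n_tracts=120, seed=11)
    panel, truth = pi.simulate_intervened_city(cfg, n_intervened=30)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def fitted(city):
    """EFA-fitted, labeled, CFA-confirmed model for the session city."""
    cfg, panel, truth = city
    fit_panel = panel.subset_years(FIT_YEARS)
    split = pi.split_halves(panel, seed=11)
    model, efa_report = pi.run_efa(fit_panel.subset_tracts(split.efa_tracts), seed=11)
    model = pi.label_factors(model, panel.catalog)
    cfa_report = pi.run_cfa(model, fit_panel.subset_tracts(split.cfa_tracts))
    return model, efa_report, cfa_report


def copy_model(model: FactorModel) -> FactorModel:
    return FactorModel.from_dict(model.to_dict())


@pytest.fixture()
def model_copy(fitted):
    return copy_model(fitted[0])


def make_stub_model(rng: np.random.Generator | None = None):
    """Minimal 3-variable, 3-factor model with identity scoring.

    The DBC score equals the demographic variable, the BPH score equals the
    mileage variable, and the health score equals the outcome variable, with
    identity standardization throughout — so tests can place tracts at exact
    factor-score coordinates by writing panel values.
    """
    V = pi.VariableCategory
    catalog = [
        pi.VariableSpec("dbc_var", V.ACS_DEMOGRAPHIC, ""),
        pi.VariableSpec("mileage_var", V.PATH_MILEAGE, "miles"),
        pi.VariableSpec("diabetes", V.CDC_HEALTH_OUTCOME, "%"),
    ]
    loadings = np.array(
        [
            [0.9, 0.0, 0.0],  # dbc_var -> factor 0
            [0.0, 0.0, 0.9],  # mileage_var -> factor 2
            [0.0, 0.9, 0.0],  # diabetes -> factor 1
        ]
    )
    weights = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0],
            [0.0, 1.0, 0.0],
        ]
    )
    return pi.FactorModel(
        retained_vars=["dbc_var", "mileage_var", "diabetes"],
        n_factors=3,
        loadings=loadings,
        assignment={"dbc_var": 0, "mileage_var": 2, "diabetes": 1},
        factor_correlations=np.eye(3),
        scoring_weights=weights,
        var_means=np.zeros(3),
        var_sds=np.ones(3),
        score_means=np.zeros(3),
        score_sds=np.ones(3),
        labels={0: "DBC", 1: "health", 2: "BPH"},
        catalog=catalog,
    )


def make_stub_panel(dbc, bph, outcome, year=2016):
    """Panel whose stub-model scores equal the given coordinates."""
    n = len(dbc)
    tracts = [f"{10000000000 + i:011d}" for i in range(n)]
    data = pd.DataFrame(
        {
            "tract_id": tracts,
            "year": year,
            "dbc_var": list(dbc),
            "mileage_var": list(bph),
            "diabetes": list(outcome),
        }
    )
    catalog = make_stub_model().catalog
    return pi.CityPanel(data, catalog), tracts
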