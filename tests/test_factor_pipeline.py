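"""Iterative EFA filtering, factor labeling, and CFA confirmation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pathimpact as pi
from pathimpact.city_panel import VariableCategory as V
from pathimpact.factor_pipeline import FactorModel, rotate_quartimin

from conftest import FIT_YEARS, copy_model

DISTRACTORS = {"pct_long_commute", "annual_checkup_pct"}


def _planted_fit(seed, n_tracts=150, **cfg_kwargs):
    cfg = pi.SyntheticConfig(n_tracts=n_tracts, seed=seed, **cfg_kwargs)
    panel, truth = pi.generate_city(cfg)
    model, report = pi.run_efa(panel.subset_years(FIT_YEARS), seed=seed)
    return cfg, panel, truth, model, report


class TestRunEfa:
    def test_planted_structure_recovered_and_distractors_discarded(self):
        cfg, panel, truth, model, report = _planted_fit(seed=21, n_tracts=200)
        labeled = pi.label_factors(model, panel.catalog)
        assert not (DISTRACTORS & set(model.retained_vars))
        assert {v for v, _, _ in report.discarded} == DISTRACTORS
        for var, factor in truth.assignment_true.items():
            assert labeled.labels[labeled.assignment[var]] == factor

    def test_clean_data_terminates_in_one_iteration(self):
        cfg = pi.SyntheticConfig(n_tracts=150, seed=13, distractors=[])
        panel, _ = pi.generate_city(cfg)
        _, report = pi.run_efa(panel.subset_years(FIT_YEARS), seed=13)
        assert report.iterations == 1
        assert report.discarded == []

    def test_pure_noise_raises_requirements_unmet(self):
        rng = np.random.default_rng(5)
        n = 80 * 5
        names_cats = [
            ("v_acs1", V.ACS_DEMOGRAPHIC), ("v_acs2", V.ACS_DEMOGRAPHIC),
            ("v_out1", V.CDC_HEALTH_OUTCOME), ("v_out2", V.CDC_HEALTH_OUTCOME),
            ("v_mileage", V.PATH_MILEAGE), ("v_use1", V.PATH_USE),
            ("v_use2", V.PATH_USE), ("v_beh", V.CDC_HEALTH_BEHAVIOR),
            ("v_stat", V.CDC_HEALTH_STATUS),
        ]
        data = pd.DataFrame(
            {"tract_id": [f"{10**10 + i // 5:011d}" for i in range(n)],
             "year": [2011 + i % 5 for i in range(n)]}
        )
        for name, _ in names_cats:
            data[name] = rng.standard_normal(n)
        panel = pi.CityPanel(data, [pi.VariableSpec(nm, c) for nm, c in names_cats])
        with pytest.raises(pi.RequirementsUnmetError):
            pi.run_efa(panel, seed=5)

    def test_candidate_set_preconditions(self, city):
        _, panel, _ = city
        fit_panel = panel.subset_years(FIT_YEARS)
        no_mileage = [v for v in panel.variables if v != panel.mileage_variable]
        with pytest.raises(ValueError, match="mileage"):
            pi.run_efa(fit_panel, candidate_vars=no_mileage, seed=0)

    def test_retained_loadings_respect_thresholds(self, fitted):
        """Assigned |pattern| > 0.5 and off-factor |pattern| < 0.5 throughout."""
        model, _, _ = fitted
        for i, var in enumerate(model.retained_vars):
            row = np.abs(model.loadings[i])
            j = model.assignment[var]
            assert row[j] > 0.5
            assert np.delete(row, j).max() < 0.5

    def test_each_labeled_factor_has_three_variables(self, fitted):
        model, _, _ = fitted
        for j in range(model.n_factors):
            assert len(model.variables_of_factor(j)) >= 3

    def test_orthogonal_factors_yield_small_factor_correlations(self):
        for seed in (31, 32):
            cfg = pi.SyntheticConfig(
                n_tracts=500, seed=seed, factor_corr=np.eye(3),
                trend_dbc=0.0, trend_bph=0.0,
            )
            panel, _ = pi.generate_city(cfg)
            model, _ = pi.run_efa(panel.subset_years(FIT_YEARS), seed=seed)
            off = model.factor_correlations[~np.eye(model.n_factors, dtype=bool)]
            assert np.abs(off).max() < 0.15

    def test_discard_iterations_are_monotone(self):
        _, _, _, _, report = _planted_fit(seed=22)
        iters = [it for _, it, _ in report.discarded]
        assert iters == sorted(iters)
        assert report.iterations <= 14  # |candidate set|


class TestRotation:
    def test_quartimin_recovers_simple_structure(self):
        """Rotating a randomly mixed simple-structure matrix restores it."""
        rng = np.random.default_rng(0)
        L_true = np.zeros((9, 3))
        for j in range(3):
            L_true[3 * j : 3 * j + 3, j] = 0.8
        T = rng.standard_normal((3, 3))
        T /= np.sqrt((T**2).sum(axis=0))
        A = L_true @ T.T  # an arbitrarily rotated version
        L_rot, Phi = rotate_quartimin(A)
        # permutation/sign aside, each row should have one dominant loading
        assert (np.abs(L_rot).max(axis=1) > 0.7).all()
        assert np.partition(np.abs(L_rot), -2, axis=1)[:, -2].max() < 0.1
        assert np.allclose(np.diag(Phi), 1.0)


def _label_stub(vars_cats_loads, assignment, n_factors=3):
    """Model skeleton for label tests: (name, category, loading row)."""
    names = [n for n, _, _ in vars_cats_loads]
    loadings = np.array([l for _, _, l in vars_cats_loads], dtype=float)
    p = len(names)
    return FactorModel(
        retained_vars=names,
        n_factors=n_factors,
        loadings=loadings,
        assignment=dict(zip(names, assignment)),
        factor_correlations=np.eye(n_factors),
        scoring_weights=np.zeros((p, n_factors)),
        var_means=np.zeros(p),
        var_sds=np.ones(p),
        score_means=np.zeros(n_factors),
        score_sds=np.ones(n_factors),
        catalog=[pi.VariableSpec(n, c) for n, c, _ in vars_cats_loads],
    )


class TestLabelFactors:
    def test_unanimous_majorities(self):
        rows = [
            ("a1", V.ACS_DEMOGRAPHIC, (0.9, 0, 0)),
            ("a2", V.ACS_DEMOGRAPHIC, (0.8, 0, 0)),
            ("a3", V.ACS_DEMOGRAPHIC, (0.85, 0, 0)),
            ("a4", V.ACS_DEMOGRAPHIC, (0.7, 0, 0)),
            ("h1", V.CDC_HEALTH_OUTCOME, (0, 0.9, 0)),
            ("h2", V.CDC_HEALTH_OUTCOME, (0, 0.8, 0)),
            ("h3", V.CDC_HEALTH_STATUS, (0, 0.7, 0)),
            ("b1", V.PATH_MILEAGE, (0, 0, 0.9)),
            ("b2", V.PATH_USE, (0, 0, 0.8)),
            ("b3", V.PATH_USE, (0, 0, 0.7)),
        ]
        model = _label_stub(rows, [0, 0, 0, 0, 1, 1, 1, 2, 2, 2])
        labeled = pi.label_factors(model, model.catalog)
        assert labeled.labels == {0: "DBC", 1: "health", 2: "BPH"}

    def test_tie_broken_by_mean_loading(self):
        # factor 0: 2 CDC + 2 ACS variables; CDC loadings larger => health
        rows = [
            ("c1", V.CDC_HEALTH_OUTCOME, (0.9, 0, 0)),
            ("c2", V.CDC_HEALTH_OUTCOME, (0.85, 0, 0)),
            ("a1", V.ACS_DEMOGRAPHIC, (0.6, 0, 0)),
            ("a2", V.ACS_DEMOGRAPHIC, (0.55, 0, 0)),
            ("a3", V.ACS_DEMOGRAPHIC, (0, 0.9, 0)),
            ("a4", V.ACS_DEMOGRAPHIC, (0, 0.8, 0)),
            ("a5", V.ACS_DEMOGRAPHIC, (0, 0.85, 0)),
            ("b1", V.PATH_MILEAGE, (0, 0, 0.9)),
            ("b2", V.PATH_USE, (0, 0, 0.8)),
            ("b3", V.PATH_USE, (0, 0, 0.85)),
        ]
        model = _label_stub(rows, [0, 0, 0, 0, 1, 1, 1, 2, 2, 2])
        labeled = pi.label_factors(model, model.catalog)
        assert labeled.labels[0] == "health"
        assert labeled.labels[1] == "DBC"

    def test_bph_factor_without_mileage_variable_rejected(self):
        rows = [
            ("a1", V.ACS_DEMOGRAPHIC, (0.9, 0, 0)),
            ("a2", V.ACS_DEMOGRAPHIC, (0.8, 0, 0)),
            ("a3", V.ACS_DEMOGRAPHIC, (0.85, 0, 0)),
            ("h1", V.CDC_HEALTH_OUTCOME, (0, 0.9, 0)),
            ("h2", V.CDC_HEALTH_OUTCOME, (0, 0.8, 0)),
            ("h3", V.CDC_HEALTH_OUTCOME, (0, 0.85, 0)),
            ("u1", V.PATH_USE, (0, 0, 0.9)),
            ("u2", V.PATH_USE, (0, 0, 0.8)),
            ("u3", V.PATH_USE, (0, 0, 0.85)),
        ]
        model = _label_stub(rows, [0, 0, 0, 1, 1, 1, 2, 2, 2])
        with pytest.raises(pi.RequirementsUnmetError, match="mileage"):
            pi.label_factors(model, model.catalog)

    def test_missing_label_group_rejected(self):
        rows = [
            ("a1", V.ACS_DEMOGRAPHIC, (0.9, 0, 0)),
            ("a2", V.ACS_DEMOGRAPHIC, (0.8, 0, 0)),
            ("a3", V.ACS_DEMOGRAPHIC, (0.85, 0, 0)),
            ("a4", V.ACS_DEMOGRAPHIC, (0, 0.9, 0)),
            ("a5", V.ACS_DEMOGRAPHIC, (0, 0.8, 0)),
            ("a6", V.ACS_DEMOGRAPHIC, (0, 0.85, 0)),
            ("b1", V.PATH_MILEAGE, (0, 0, 0.9)),
            ("b2", V.PATH_USE, (0, 0, 0.8)),
            ("b3", V.PATH_USE, (0, 0, 0.85)),
        ]
        model = _label_stub(rows, [0, 0, 0, 1, 1, 1, 2, 2, 2])
        with pytest.raises(pi.RequirementsUnmetError, match="health"):
            pi.label_factors(model, model.catalog)


class TestRunCfa:
    def test_holdout_half_confirms_planted_model(self, fitted):
        _, _, cfa_report = fitted
        assert cfa_report.confirmed
        idx = cfa_report.fit_indices
        assert idx["CFI"] >= 0.90 and idx["RMSEA"] <= 0.08

    def test_confirmation_updates_loadings(self, city):
        _, panel, _ = city
        fit_panel = panel.subset_years(FIT_YEARS)
        split = pi.split_halves(panel, seed=11)
        model, _ = pi.run_efa(fit_panel.subset_tracts(split.efa_tracts), seed=11)
        model = pi.label_factors(model, panel.catalog)
        before = model.loadings.copy()  # oblique pattern from the EFA half
        report = pi.run_cfa(model, fit_panel.subset_tracts(split.cfa_tracts))
        assert report.confirmed
        assert not np.allclose(model.loadings, before)
        # CFA imposes strict simple structure: one loading per variable
        for i, var in enumerate(model.retained_vars):
            j = model.assignment[var]
            assert abs(model.loadings[i, j]) > 0.5
            assert np.allclose(np.delete(model.loadings[i], j), 0.0)

    def test_permuted_columns_are_not_confirmed(self, city, fitted):
        """Shuffling each variable independently destroys the structure."""
        _, panel, _ = city
        model = copy_model(fitted[0])
        fit_panel = panel.subset_years(FIT_YEARS)
        half = fit_panel.subset_tracts(pi.split_halves(panel, seed=11).cfa_tracts)
        rng = np.random.default_rng(0)
        data = half.data.copy()
        for var in model.retained_vars:
            data[var] = rng.permutation(data[var].to_numpy())
        report = pi.run_cfa(model, pi.CityPanel(data, half.catalog))
        assert not report.confirmed

    def test_self_consistency_on_the_efa_half(self, city, fitted):
        _, panel, _ = city
        model = copy_model(fitted[0])
        fit_panel = panel.subset_years(FIT_YEARS)
        half = fit_panel.subset_tracts(pi.split_halves(panel, seed=11).efa_tracts)
        report = pi.run_cfa(model, half)
        assert report.confirmed


def test_model_json_roundtrip(fitted):
    model, _, _ = fitted
    back = FactorModel.from_dict(model.to_dict())
    assert back.retained_vars == model.retained_vars
    assert back.assignment == model.assignment
    assert back.labels == model.labels
    np.testing.assert_allclose(back.loadings, model.loadings)
    np.testing.assert_allclose(back.scoring_weights, model.scoring_weights)
    assert back.catalog == model.catalog
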