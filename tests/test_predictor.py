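"""Neighbor-matching prediction: hand-checked cases, oracle equivalence, sweep."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pathimpact as pi

from conftest import copy_model, make_stub_model, make_stub_panel


def _query(tract, miles=0.0, x=0.5, year=2016):
    return pi.PredictionQuery(tract_id=tract, added_miles=miles, x=x, year=year)


class TestHandEnumeratedCases:
    """Four tracts A-D at exact score coordinates, checked by hand.

    DBC scores A=0.0, B=0.2, C=0.4, D=1.0; post-addition BPH scores A=0.0,
    B=0.3, C=0.8, D=0.1.  With x=0.5 the DBC ball around A holds {B, C},
    the BPH ball holds {B, D}; the intersection is {B}.
    """

    def _setup(self, diabetes):
        model = make_stub_model()
        panel, tracts = make_stub_panel(
            dbc=[0.0, 0.2, 0.4, 1.0], bph=[0.0, 0.3, 0.8, 0.1], outcome=diabetes
        )
        scores = pi.compute_scores(model, panel, 2016)
        return model, panel, scores, tracts

    def test_single_neighbor_positive_improvement(self):
        model, panel, scores, t = self._setup(diabetes=[12, 10, 9, 8])
        result = pi.predict_improvements(model, panel, scores, _query(t[0]))
        assert result.neighbors == [t[1]]
        s = result.outcomes["diabetes"]
        assert s.improvements == [2.0]
        assert s.min == s.mean == s.median == s.max == 2.0
        assert not s.empty_flag

    def test_negative_difference_discarded_leaves_empty_distribution(self):
        model, panel, scores, t = self._setup(diabetes=[12, 15, 9, 8])
        result = pi.predict_improvements(model, panel, scores, _query(t[0]))
        s = result.outcomes["diabetes"]
        assert s.empty_flag
        assert s.improvements == []
        assert s.min == s.mean == s.median == s.max == s.sd == 0.0

    def test_large_x_admits_every_other_tract(self):
        model, panel, scores, t = self._setup(diabetes=[12, 10, 9, 8])
        result = pi.predict_improvements(model, panel, scores, _query(t[0], x=10))
        assert set(result.neighbors) == set(t[1:])
        assert result.outcomes["diabetes"].improvements == [2.0, 3.0, 4.0]

    def test_x_zero_yields_empty_neighbor_set(self):
        model, panel, scores, t = self._setup(diabetes=[12, 10, 9, 8])
        result = pi.predict_improvements(model, panel, scores, _query(t[0], x=0.0))
        assert result.neighbor_count == 0
        assert result.outcomes["diabetes"].empty_flag

    def test_ties_at_exactly_x_are_included(self):
        model, panel, scores, t = self._setup(diabetes=[12, 10, 9, 8])
        result = pi.predict_improvements(model, panel, scores, _query(t[0], x=0.4))
        # C sits at DBC distance exactly 0.4 but BPH distance 0.8: excluded;
        # B at (0.2, 0.3): included; D at (1.0, 0.1): DBC too far
        assert result.neighbors == [t[1]]
        result = pi.predict_improvements(model, panel, scores, _query(t[3], x=0.9))
        # from D: DBC ball {B(0.8), C(0.6)}... B at |1.0-0.2|=0.8 <= 0.9 in,
        # BPH ball from 0.1: A(0.1), B(0.2), C(0.7) all in => {B, C}
        assert set(result.neighbors) == {t[1], t[2]}

    def test_unknown_tract_and_unlabeled_model_rejected(self):
        model, panel, scores, t = self._setup(diabetes=[12, 10, 9, 8])
        with pytest.raises(KeyError):
            pi.predict_improvements(model, panel, scores, _query("00000000000"))
        unlabeled = copy_model(model)
        unlabeled.labels = {}
        with pytest.raises(KeyError):
            pi.predict_improvements(unlabeled, panel, scores, _query(t[0]))


def _brute_force(model, panel, scores, query):
    """Independent double-loop enumeration of the five algorithm steps."""
    rows = panel.rows_for_year(query.year)
    values = {
        v: rows.loc[query.tract_id, v] for v in model.retained_vars
    }
    values[panel.mileage_variable] = (
        values[panel.mileage_variable] + query.added_miles
    )
    z = [
        (values[v] - model.var_means[i]) / model.var_sds[i]
        for i, v in enumerate(model.retained_vars)
    ]
    post = {}
    for j, label in enumerate(model.label_names):
        raw = sum(z[i] * model.scoring_weights[i, j] for i in range(len(z)))
        post[label] = (raw - model.score_means[j]) / model.score_sds[j]
    neighbors = []
    for other in scores.tract_ids:
        if other == query.tract_id:
            continue
        if abs(scores.of(other, "DBC") - post["DBC"]) > query.x:
            continue
        if abs(scores.of(other, "BPH") - post["BPH"]) > query.x:
            continue
        neighbors.append(other)
    out = {}
    for outcome in model.health_outcome_variables():
        vals = []
        for nb in neighbors:
            d = float(rows.loc[query.tract_id, outcome]) - float(rows.loc[nb, outcome])
            if d >= 0:
                vals.append(d)
        if vals:
            arr = np.asarray(vals)
            out[outcome] = dict(
                improvements=sorted(vals),
                min=arr.min(),
                mean=arr.mean(),
                median=float(np.median(arr)),
                max=arr.max(),
            )
        else:
            out[outcome] = dict(improvements=[], min=0.0, mean=0.0, median=0.0, max=0.0)
    return set(neighbors), out


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_instances(self):
        """100 random 20-tract instances agree exactly with the double loop."""
        rng = np.random.default_rng(2024)
        model = make_stub_model()
        for _ in range(100):
            panel, tracts = make_stub_panel(
                dbc=rng.normal(size=20),
                bph=rng.normal(size=20),
                outcome=rng.uniform(5, 20, size=20).round(2),
            )
            scores = pi.compute_scores(model, panel, 2016)
            query = _query(
                tract=tracts[rng.integers(20)],
                miles=float(rng.uniform(0, 2)),
                x=float(rng.uniform(0.1, 1.5)),
            )
            got = pi.predict_improvements(model, panel, scores, query)
            want_neighbors, want = _brute_force(model, panel, scores, query)
            assert set(got.neighbors) == want_neighbors
            for outcome, summary in got.outcomes.items():
                w = want[outcome]
                assert sorted(summary.improvements) == pytest.approx(w["improvements"])
                for stat in ("min", "mean", "median", "max"):
                    assert getattr(summary, stat) == pytest.approx(w[stat])

    def test_summary_ordering_invariants(self, city, fitted):
        _, panel, _ = city
        model = copy_model(fitted[0])
        scores = pi.compute_scores(model, panel, 2015, refit_standardization=True)
        for tract in panel.tract_ids[:10]:
            result = pi.predict_improvements(
                model, panel, scores, _query(tract, miles=1.0, year=2015)
            )
            for s in result.outcomes.values():
                assert s.min <= s.median <= s.max
                assert s.min <= s.mean <= s.max
                assert all(v >= 0 for v in s.improvements)


class TestSweep:
    def test_grid_construction_includes_final_partial_step(self):
        assert pi.increment_grid(0.25, 0.10) == pytest.approx([0.10, 0.20, 0.25])
        assert pi.increment_grid(0.30, 0.10) == pytest.approx([0.10, 0.20, 0.30])
        assert pi.increment_grid(0.05, 0.10) == pytest.approx([0.05])
        with pytest.raises(ValueError):
            pi.increment_grid(0.0, 0.1)

    def test_best_median_is_max_over_trace(self, city, fitted):
        _, panel, _ = city
        model = copy_model(fitted[0])
        scores = pi.compute_scores(model, panel, 2015, refit_standardization=True)
        sweep = pi.sweep_increments(
            model, panel, scores, panel.tract_ids[3], total_miles=1.0, year=2015
        )
        assert len(sweep.grid) == 10
        for outcome, best in sweep.best_median.items():
            medians = [r.outcomes[outcome].median for r in sweep.trace]
            assert best == pytest.approx(max(medians))

    def test_refining_the_grid_never_lowers_the_best_median(self, city, fitted):
        _, panel, _ = city
        model = copy_model(fitted[0])
        scores = pi.compute_scores(model, panel, 2015, refit_standardization=True)
        tract = panel.tract_ids[7]
        coarse = pi.sweep_increments(
            model, panel, scores, tract, total_miles=1.0, step=0.25, year=2015
        )
        fine = pi.sweep_increments(
            model, panel, scores, tract, total_miles=1.0, step=0.05, year=2015
        )
        # the fine grid contains every coarse point, so its max cannot drop
        assert set(np.round(coarse.grid, 6)) <= set(np.round(fine.grid, 6))
        for outcome in coarse.best_median:
            assert fine.best_median[outcome] >= coarse.best_median[outcome] - 1e-12
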