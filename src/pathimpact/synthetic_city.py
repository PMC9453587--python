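"""Synthetic multi-year city panels with planted three-factor structure.

The generator emulates the kind of tract-level panel the factor pipeline is
designed for: observed ACS-style demographics, CDC-style health-outcome
prevalences, and path mileage / path-use counts, all driven by three
correlated latent factors —

* **DBC** — demographics and background characteristics,
* **health** — the tract's adverse-health burden (higher = worse), and
* **BPH** — bicycling and pedestrian habits, which owns the mileage variable.

Each observed variable is ``scale * (loading . factor + noise) + mean``,
prevalences clipped to [0, 100].  Distractor variables cross-load weakly on
two factors so that the communality filter has something real to discard.
A mileage intervention applied to a subset of tracts produces a lagged,
gated, saturating drop in the health-outcome prevalences; the planted factor
scores, variable assignment and per-tract drops are exported as ground truth
for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .city_panel import (
    CityPanel,
    VariableCategory,
    VariableSpec,
)

FACTOR_NAMES = ("DBC", "health", "BPH")


@dataclass(frozen=True)
class EffectSpec:
    """Shape of the planted intervention effect on health outcomes.

    The drop in an outcome's prevalence at ``lag`` years after the
    intervention is ``max_drop * delta / (delta + half_sat)`` for a tract
    whose true DBC factor score is at least ``dbc_gate``, and zero below the
    gate — a saturating dose response with a hard demographic threshold.

    Parameters
    ----------
    max_drop
        Asymptotic prevalence drop, percentage points.
    half_sat
        Added mileage at which half of ``max_drop`` is realised, miles.
    dbc_gate
        DBC factor-score threshold (SD units) below which paths do nothing.
    lag
        Years between installation and the fully realised outcome change.
    """

    max_drop: float = 3.0
    half_sat: float = 0.5
    dbc_gate: float = -1.0  # paths fail only in the most disadvantaged ~16%
    lag: int = 5

    def __post_init__(self) -> None:
        if self.max_drop < 0:
            raise ValueError("max_drop must be >= 0")
        if self.half_sat <= 0:
            raise ValueError("half_sat must be > 0")

    def drop(self, added_miles: float, dbc_score: float) -> float:
        """Planted prevalence drop (noiseless), percentage points."""
        if added_miles <= 0 or dbc_score < self.dbc_gate:
            return 0.0
        return self.max_drop * added_miles / (added_miles + self.half_sat)


@dataclass(frozen=True)
class SyntheticVariable:
    """One generated observed variable: factor loadings and affine scale."""

    name: str
    category: VariableCategory
    loadings: tuple[float, float, float]  # on (DBC, health, BPH)
    mean: float = 0.0
    scale: float = 1.0

    @property
    def primary_factor(self) -> str:
        return FACTOR_NAMES[int(np.argmax(np.abs(self.loadings)))]


def _default_variables() -> list[SyntheticVariable]:
    """Twelve signal variables (four per factor) at the study loadings of 0.9.

    Means and scales are set to plausible tract-level magnitudes: prevalences
    around the national urban averages, mileage a couple of miles per tract,
    use counts in the hundreds.  The health factor is an adverse-burden axis,
    so health-outcome loadings are positive on it.
    """
    V = VariableCategory
    return [
        # DBC signal (ACS demographics; higher = more advantaged)
        SyntheticVariable("pct_bachelors", V.ACS_DEMOGRAPHIC, (0.9, 0, 0), 31.0, 10.0),
        SyntheticVariable("median_income_k", V.ACS_DEMOGRAPHIC, (0.9, 0, 0), 62.0, 18.0),
        SyntheticVariable("pct_employed", V.ACS_DEMOGRAPHIC, (0.9, 0, 0), 60.0, 8.0),
        SyntheticVariable("pct_insured", V.ACS_DEMOGRAPHIC, (0.9, 0, 0), 88.0, 5.0),
        # health signal (CDC 500 Cities outcome prevalences, %); within-city
        # tract dispersions are kept in the 1.5-3.5 point band so the planted
        # path effects are comparable in standardized units across outcomes
        SyntheticVariable("diabetes_pct", V.CDC_HEALTH_OUTCOME, (0, 0.9, 0), 11.0, 2.5),
        SyntheticVariable(
            "high_blood_pressure_pct", V.CDC_HEALTH_OUTCOME, (0, 0.9, 0), 32.0, 3.5
        ),
        SyntheticVariable(
            "poor_physical_health_pct", V.CDC_HEALTH_OUTCOME, (0, 0.9, 0), 13.0, 3.0
        ),
        SyntheticVariable("stroke_pct", V.CDC_HEALTH_OUTCOME, (0, 0.9, 0), 3.5, 1.5),
        # BPH signal (municipal mileage + use counts)
        SyntheticVariable("path_mileage_mi", V.PATH_MILEAGE, (0, 0, 0.9), 2.0, 1.2),
        SyntheticVariable("strava_trip_count", V.PATH_USE, (0, 0, 0.9), 500.0, 180.0),
        SyntheticVariable("counter_trip_count", V.PATH_USE, (0, 0, 0.9), 320.0, 120.0),
        SyntheticVariable("weekend_trip_count", V.PATH_USE, (0, 0, 0.9), 150.0, 60.0),
    ]


def _default_distractors() -> list[SyntheticVariable]:
    """Two straddling variables cross-loading 0.45/0.45 on a factor pair.

    Each loads equally on two factors whose correlation runs the other way
    (long commutes pair affluence with worse health; checkup uptake pairs
    care-seeking burden with active habits), so the variable measures a
    contrast between constructs and shares well under half its variance
    with every factor — exactly the kind of in-between variable the
    communality filter exists to discard.
    """
    V = VariableCategory
    return [
        SyntheticVariable(
            "pct_long_commute", V.ACS_DEMOGRAPHIC, (0.45, 0.45, 0.0), 28.0, 9.0
        ),
        SyntheticVariable(
            "annual_checkup_pct", V.CDC_PREVENTION, (0.0, 0.45, 0.45), 70.0, 7.0
        ),
    ]


def _default_factor_corr() -> np.ndarray:
    # advantaged demographics go with lower adverse burden and more path use;
    # tract-level SES-health gradients are strong, so the default
    # correlations are substantial (the method presumes one coherent system)
    return np.array(
        [
            [1.00, -0.55, 0.40],
            [-0.55, 1.00, -0.45],
            [0.40, -0.45, 1.00],
        ]
    )


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic city.

    Defaults are the conditions the recovery and evaluation suites run
    under: 200 tracts, years 2011-2021, signal loadings 0.9, two 0.45/0.45
    distractors, observation noise SD 0.3 (in factor units), a small AR(1)
    outcome drift so the no-change baseline is not trivially perfect, and a
    gated saturating intervention effect with a 5-year lag.
    """

    n_tracts: int = 200
    years: Sequence[int] = tuple(range(2011, 2022))
    factor_corr: np.ndarray = field(default_factory=_default_factor_corr)
    variables: list[SyntheticVariable] = field(default_factory=_default_variables)
    distractors: list[SyntheticVariable] = field(default_factory=_default_distractors)
    noise_sd: float = 0.3
    drift_sd: float = 0.3  # % points / year, AR(1) on outcome prevalences
    drift_rho: float = 0.8
    # secular prevalence trends (% points/year per SD of factor score):
    # advantaged and path-active tracts were already improving before any
    # intervention, and the path-linked share of that history operates
    # through the same demographic gate as the intervention effect
    trend_dbc: float = 0.10
    trend_bph: float = 0.15
    effect: EffectSpec = field(default_factory=EffectSpec)
    seed: int = 0

    @property
    def all_variables(self) -> list[SyntheticVariable]:
        return list(self.variables) + list(self.distractors)

    def catalog(self) -> list[VariableSpec]:
        units = {
            VariableCategory.PATH_MILEAGE: "miles",
            VariableCategory.PATH_USE: "trips/year",
        }
        return [
            VariableSpec(v.name, v.category, units.get(v.category, "%"))
            for v in self.all_variables
        ]


@dataclass
class GroundTruth:
    """Planted quantities exported for recovery tests."""

    factor_scores_true: pd.DataFrame  # index tract_id, columns DBC/health/BPH
    assignment_true: dict[str, str]  # variable -> primary factor (signal only)
    effect_applied: pd.DataFrame  # index tract_id, one column per outcome, % points
    added_miles: dict[str, float] = field(default_factory=dict)
    intervention_year: int | None = None


def truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "factor_scores_true": {
            t: {f: float(truth.factor_scores_true.loc[t, f]) for f in FACTOR_NAMES}
            for t in truth.factor_scores_true.index
        },
        "assignment_true": dict(truth.assignment_true),
        "effect_applied": {
            t: {o: float(truth.effect_applied.loc[t, o]) for o in truth.effect_applied.columns}
            for t in truth.effect_applied.index
        },
        "added_miles": {t: float(m) for t, m in truth.added_miles.items()},
        "intervention_year": truth.intervention_year,
    }


def truth_from_dict(d: dict) -> GroundTruth:
    return GroundTruth(
        factor_scores_true=pd.DataFrame.from_dict(
            d["factor_scores_true"], orient="index"
        )[list(FACTOR_NAMES)],
        assignment_true=dict(d["assignment_true"]),
        effect_applied=pd.DataFrame.from_dict(d["effect_applied"], orient="index"),
        added_miles={t: float(m) for t, m in d.get("added_miles", {}).items()},
        intervention_year=d.get("intervention_year"),
    )


def _tract_ids(n: int) -> list[str]:
    # synthetic 11-digit FIPS-style IDs (state 51, county 710)
    return [f"51710{i:06d}" for i in range(n)]


def generate_city(config: SyntheticConfig) -> tuple[CityPanel, GroundTruth]:
    """Generate a panel from the planted linear factor model.

    Tract factor scores are drawn once from N(0, factor_corr) and held fixed
    across years; each tract-year observation adds fresh Gaussian noise of SD
    ``noise_sd`` in factor units before the affine map to the variable's
    scale.  Prevalence variables additionally receive an AR(1) drift (in
    percentage points) and are clipped to [0, 100].  Deterministic under
    ``config.seed``.
    """
    corr = np.asarray(config.factor_corr, dtype=float)
    if corr.shape != (3, 3):
        raise ValueError("factor_corr must be 3x3")
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() <= 0:
        raise ValueError("factor_corr is not positive definite")

    rng = np.random.default_rng(config.seed)
    n, years = config.n_tracts, list(config.years)
    tracts = _tract_ids(n)

    chol = np.linalg.cholesky(corr)
    factors = rng.standard_normal((n, 3)) @ chol.T  # tract x (DBC, health, BPH)

    prevalence_vars = [
        v
        for v in config.all_variables
        if v.category in {c for c in VariableCategory if c.value.startswith("CDC")}
    ]
    drift = {v.name: np.zeros(n) for v in prevalence_vars}

    # per-tract secular slope, % points/year (negative = improving); the
    # path-linked share only operates above the demographic gate
    gate_ok = factors[:, 0] >= config.effect.dbc_gate
    slope = -(
        config.trend_dbc * factors[:, 0]
        + config.trend_bph * factors[:, 2] * gate_ok
    )

    records = []
    for k, year in enumerate(years):
        row_block = {"tract_id": tracts, "year": year}
        for v in config.all_variables:
            latent = factors @ np.asarray(v.loadings)
            latent = latent + config.noise_sd * rng.standard_normal(n)
            obs = v.mean + v.scale * latent
            if v.name in drift:
                obs = obs + drift[v.name] + slope * k
                obs = np.clip(obs, 0.0, 100.0)
            row_block[v.name] = obs
        records.append(pd.DataFrame(row_block))
        # drift evolves between years (AR(1) in % points)
        for name in drift:
            drift[name] = config.drift_rho * drift[name] + config.drift_sd * (
                rng.standard_normal(n)
            )

    data = pd.concat(records, ignore_index=True)
    panel = CityPanel(data, config.catalog())
    truth = GroundTruth(
        factor_scores_true=pd.DataFrame(factors, index=tracts, columns=FACTOR_NAMES),
        assignment_true={v.name: v.primary_factor for v in config.variables},
        effect_applied=pd.DataFrame(
            0.0,
            index=tracts,
            columns=[
                v.name
                for v in config.all_variables
                if v.category is VariableCategory.CDC_HEALTH_OUTCOME
            ],
        ),
    )
    return panel, truth


def apply_intervention(
    panel: CityPanel,
    truth: GroundTruth,
    tracts: Sequence[str],
    added_miles: Mapping[str, float],
    intervention_year: int,
    effect: EffectSpec,
) -> tuple[CityPanel, GroundTruth]:
    """Add path mileage to selected tracts and plant the lagged outcome drop.

    The mileage variable is increased from ``intervention_year`` onward
    (paths persist once built).  From ``intervention_year + effect.lag``
    onward, each health-outcome prevalence of an intervened tract is reduced
    by the gated saturating drop evaluated at the tract's *true* DBC score;
    the drops are recorded in the returned ground truth.  Outcomes stay
    clipped to [0, 100].
    """
    if intervention_year + effect.lag > max(panel.years):
        raise ValueError(
            f"panel ends {max(panel.years)}, before the effect lag "
            f"({intervention_year} + {effect.lag})"
        )
    known = set(panel.tract_ids)
    unknown = [t for t in tracts if t not in known]
    if unknown:
        raise KeyError(f"tracts not in panel: {unknown}")

    new = panel.copy()
    df = new.data
    mileage_var = panel.mileage_variable
    outcome_vars = list(truth.effect_applied.columns)

    effect_applied = truth.effect_applied.copy()
    miles_record = dict(truth.added_miles)
    for tract in tracts:
        delta = float(added_miles[tract])
        if delta < 0:
            raise ValueError(f"added_miles must be >= 0 (tract {tract})")
        miles_record[tract] = miles_record.get(tract, 0.0) + delta
        mask_tract = df["tract_id"] == tract
        df.loc[mask_tract & (df["year"] >= intervention_year), mileage_var] += delta
        dbc = float(truth.factor_scores_true.loc[tract, "DBC"])
        drop = effect.drop(delta, dbc)
        effect_applied.loc[tract, outcome_vars] += drop
        if drop > 0:
            mask_lagged = mask_tract & (df["year"] >= intervention_year + effect.lag)
            for outcome in outcome_vars:
                df.loc[mask_lagged, outcome] = np.clip(
                    df.loc[mask_lagged, outcome] - drop, 0.0, 100.0
                )

    new_truth = replace(
        truth,
        effect_applied=effect_applied,
        added_miles=miles_record,
        intervention_year=intervention_year,
    )
    return CityPanel(df, new.catalog), new_truth


def simulate_intervened_city(
    config: SyntheticConfig,
    n_intervened: int = 40,
    miles_low: float = 0.3,
    miles_high: float = 2.0,
    intervention_year: int = 2016,
) -> tuple[CityPanel, GroundTruth]:
    """Convenience wrapper: generate a city and intervene on a random subset.

    Per-tract added mileage is uniform on [miles_low, miles_high], matching
    the roughly one-mile-per-tract scale of real city path programmes.
    """
    panel, truth = generate_city(config)
    rng = np.random.default_rng(config.seed + 1)
    chosen = list(rng.choice(panel.tract_ids, size=n_intervened, replace=False))
    miles = {t: float(rng.uniform(miles_low, miles_high)) for t in chosen}
    return apply_intervention(
        panel, truth, chosen, miles, intervention_year, config.effect
    )
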