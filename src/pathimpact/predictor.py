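"""Neighbor-matching prediction of health-outcome improvements.

The five-step what-if query: (1) add the proposed path mileage to the query
tract; (2) recompute that tract's factor scores under the frozen model;
(3) collect all other tracts whose DBC score lies within a closed radius x
of the query tract's; (4) likewise for the BPH score, using the
post-addition value; (5) intersect the two neighbor sets and, for every
health-outcome variable in the model, take the differences

    query tract's prevalence  -  neighbor's prevalence,

discarding negatives.  A positive difference means a tract that is similar
demographically and in realized path habits carries a lower adverse-outcome
prevalence — the plausible benefit of the added mileage.  The distribution
is summarised by min / mean / median / max / SD; an empty distribution is
reported as zeros with a flag, marking places where added paths are
unlikely to be an effective intervention.

The evaluation variant sweeps the requested mileage in 0.10-mile increments
and reports, per outcome, the largest median improvement over the sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .city_panel import CityPanel
from .factor_pipeline import FactorModel
from .scoring import FactorScores, score_modified_tract


@dataclass(frozen=True)
class PredictionQuery:
    """One what-if question: tract, proposed mileage, similarity radius."""

    tract_id: str
    added_miles: float
    x: float = 0.50
    year: int = 2016

    def __post_init__(self) -> None:
        if self.added_miles < 0:
            raise ValueError("added_miles must be >= 0")
        # x = 0 is a degenerate but valid query: the radius-zero ball admits
        # only exact score ties, so neighbor sets are (almost surely) empty
        if self.x < 0:
            raise ValueError("threshold x must be >= 0")


@dataclass
class ImprovementSummary:
    """Distribution of nonnegative hypothesized improvements, % points."""

    improvements: list[float]
    min: float
    mean: float
    median: float
    max: float
    sd: float
    empty_flag: bool

    @classmethod
    def from_values(cls, values: list[float]) -> "ImprovementSummary":
        if not values:
            return cls([], 0.0, 0.0, 0.0, 0.0, 0.0, True)
        arr = np.asarray(values, dtype=float)
        return cls(
            improvements=[float(v) for v in values],
            min=float(arr.min()),
            mean=float(arr.mean()),
            median=float(np.median(arr)),
            max=float(arr.max()),
            sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            empty_flag=False,
        )


@dataclass
class PredictionResult:
    """Per-outcome improvement distributions plus the matched neighbor set."""

    query: PredictionQuery
    neighbor_count: int
    neighbors: list[str]
    outcomes: dict[str, ImprovementSummary]
    post_scores: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "tract_id": self.query.tract_id,
            "added_miles": self.query.added_miles,
            "x": self.query.x,
            "year": self.query.year,
            "neighbor_count": self.neighbor_count,
            "neighbors": self.neighbors,
            "post_scores": self.post_scores,
            "outcomes": {
                name: {
                    "min": s.min,
                    "mean": s.mean,
                    "median": s.median,
                    "max": s.max,
                    "sd": s.sd,
                    "n": len(s.improvements),
                    "empty": s.empty_flag,
                }
                for name, s in self.outcomes.items()
            },
        }


def predict_improvements(
    model: FactorModel,
    panel: CityPanel,
    scores: FactorScores,
    query: PredictionQuery,
) -> PredictionResult:
    """Run the five-step neighbor-matching query for one tract.

    ``scores`` are the city's current standardized factor scores (computed
    once, standardization then frozen on the model); only the query tract is
    rescored after the mileage addition.  Threshold comparisons use a closed
    ball, so ties at exactly x count as neighbors.
    """
    for label in ("DBC", "health", "BPH"):
        model.factor_index(label)  # raises KeyError if unlabeled
    if query.tract_id not in scores.tract_ids:
        raise KeyError(f"unknown tract {query.tract_id!r}")

    post = score_modified_tract(
        model, panel, query.tract_id, query.year, query.added_miles
    )
    dbc_q, bph_q = post["DBC"], post["BPH"]

    frame = scores.scores
    others = frame.index[frame.index != query.tract_id]
    dbc_near = np.abs(frame.loc[others, "DBC"] - dbc_q) <= query.x
    bph_near = np.abs(frame.loc[others, "BPH"] - bph_q) <= query.x
    neighbors = list(others[np.asarray(dbc_near) & np.asarray(bph_near)])

    rows = panel.rows_for_year(query.year)
    outcomes: dict[str, ImprovementSummary] = {}
    for outcome in model.health_outcome_variables():
        q_val = float(rows.loc[query.tract_id, outcome])
        diffs = [q_val - float(rows.loc[nb, outcome]) for nb in neighbors]
        outcomes[outcome] = ImprovementSummary.from_values(
            [d for d in diffs if d >= 0]
        )
    return PredictionResult(
        query=query,
        neighbor_count=len(neighbors),
        neighbors=neighbors,
        outcomes=outcomes,
        post_scores=post,
    )


@dataclass
class SweepResult:
    """Trace of the increment sweep and the best median per outcome."""

    tract_id: str
    total_miles: float
    step: float
    grid: list[float]
    trace: list[PredictionResult]
    best_median: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "tract_id": self.tract_id,
            "total_miles": self.total_miles,
            "step": self.step,
            "grid": self.grid,
            "best_median": self.best_median,
            "trace": [r.to_dict() for r in self.trace],
        }


def increment_grid(total_miles: float, step: float = 0.10) -> list[float]:
    """Mileage grid {step, 2*step, ...} plus the full requested amount."""
    if total_miles <= 0:
        raise ValueError("total_miles must be > 0")
    if step <= 0:
        raise ValueError("step must be > 0")
    n_full = int(np.floor(total_miles / step + 1e-9))
    grid = [round(step * k, 10) for k in range(1, n_full + 1)]
    if not grid or not np.isclose(grid[-1], total_miles):
        grid.append(float(total_miles))
    return grid


def sweep_increments(
    model: FactorModel,
    panel: CityPanel,
    scores: FactorScores,
    tract_id: str,
    total_miles: float,
    x: float = 0.50,
    step: float = 0.10,
    year: int = 2016,
) -> SweepResult:
    """Run the query at every 0.10-mile increment up to ``total_miles``.

    Per outcome, reports the largest median improvement attained anywhere on
    the grid — operationalising the assumption that more mileage is never
    detrimental to the expected improvement.
    """
    grid = increment_grid(total_miles, step)
    trace = [
        predict_improvements(
            model, panel, scores, PredictionQuery(tract_id, miles, x, year)
        )
        for miles in grid
    ]
    best: dict[str, float] = {}
    for result in trace:
        for outcome, summary in result.outcomes.items():
            best[outcome] = max(best.get(outcome, 0.0), summary.median)
    return SweepResult(
        tract_id=tract_id,
        total_miles=float(total_miles),
        step=float(step),
        grid=grid,
        trace=trace,
        best_median=best,
    )
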