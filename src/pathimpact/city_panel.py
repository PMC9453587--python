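"""Census-tract-by-year panel data model and I/O.

A :class:`CityPanel` is the universal input to the factor pipeline: one row
per (tract, year), one column per observed variable, plus a catalog tagging
each variable with the data-source category it came from (ACS demographics,
CDC 500 Cities prevalences, municipal path mileage, path-use counts).
Tract identifiers are opaque 11-digit FIPS strings; geometry is assumed to
have been joined upstream.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pathimpact")

#: Exact international mile, in kilometres.
KM_PER_MILE = 1.609344

_FIPS_RE = re.compile(r"^\d{11}$")

ID_COLUMNS = ("tract_id", "year")


class PanelFormatError(ValueError):
    """CSV or catalog file does not have the expected shape."""


class PanelValidationError(ValueError):
    """Panel content violates a structural invariant."""


class VariableCategory(str, Enum):
    """Data-source category of an observed variable."""

    ACS_DEMOGRAPHIC = "ACS_demographic"
    CDC_HEALTH_OUTCOME = "CDC_health_outcome"
    CDC_HEALTH_BEHAVIOR = "CDC_health_behavior"
    CDC_PREVENTION = "CDC_prevention"
    CDC_HEALTH_STATUS = "CDC_health_status"
    PATH_MILEAGE = "path_mileage"
    PATH_USE = "path_use"


#: Category groups backing the three required latent factors.
DBC_CATEGORIES = frozenset({VariableCategory.ACS_DEMOGRAPHIC})
HEALTH_CATEGORIES = frozenset(
    {
        VariableCategory.CDC_HEALTH_OUTCOME,
        VariableCategory.CDC_HEALTH_BEHAVIOR,
        VariableCategory.CDC_PREVENTION,
        VariableCategory.CDC_HEALTH_STATUS,
    }
)
BPH_CATEGORIES = frozenset({VariableCategory.PATH_MILEAGE, VariableCategory.PATH_USE})

#: Categories whose values are prevalence percentages, bounded in [0, 100].
PREVALENCE_CATEGORIES = HEALTH_CATEGORIES


@dataclass(frozen=True)
class VariableSpec:
    """One observed variable: its name, source category, and units."""

    name: str
    category: VariableCategory
    units: str = ""


def miles_to_km(miles: float) -> float:
    """Convert miles to kilometres using the exact factor 1.609344."""
    return miles * KM_PER_MILE


@dataclass
class CityPanel:
    """Tract-year panel of observed variables with a category catalog.

    Parameters
    ----------
    data
        DataFrame with columns ``tract_id`` (11-digit FIPS string), ``year``
        (int) and one numeric column per catalog variable.
    catalog
        One :class:`VariableSpec` per observed variable.
    """

    data: pd.DataFrame
    catalog: list[VariableSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self._check_invariants()

    # -- structural invariants -------------------------------------------

    def _check_invariants(self) -> None:
        cols = list(self.data.columns)
        for required in ID_COLUMNS:
            if required not in cols:
                raise PanelFormatError(f"panel is missing mandatory column {required!r}")
        catalog_names = [v.name for v in self.catalog]
        if len(set(catalog_names)) != len(catalog_names):
            raise PanelFormatError("catalog contains duplicate variable names")
        extra = [c for c in cols if c not in ID_COLUMNS and c not in catalog_names]
        if extra:
            raise PanelFormatError(
                f"panel has columns not in the catalog: {', '.join(extra)}"
            )
        missing = [n for n in catalog_names if n not in cols]
        if missing:
            raise PanelFormatError(
                f"catalog variables absent from the panel: {', '.join(missing)}"
            )
        dup = self.data.duplicated(subset=list(ID_COLUMNS))
        if dup.any():
            pairs = self.data.loc[dup, list(ID_COLUMNS)].itertuples(index=False)
            raise PanelValidationError(
                "duplicate (tract, year) rows: "
                + ", ".join(f"({t}, {y})" for t, y in pairs)
            )
        years = sorted(self.data["year"].unique())
        if years and years != list(range(years[0], years[-1] + 1)):
            raise PanelValidationError(f"years are not a contiguous range: {years}")
        n_mileage = sum(
            1 for v in self.catalog if v.category is VariableCategory.PATH_MILEAGE
        )
        if self.catalog and n_mileage != 1:
            raise PanelValidationError(
                f"expected exactly one path_mileage variable, found {n_mileage}"
            )

    # -- accessors --------------------------------------------------------

    @property
    def variables(self) -> list[str]:
        return [v.name for v in self.catalog]

    @property
    def tract_ids(self) -> list[str]:
        return sorted(self.data["tract_id"].unique())

    @property
    def n_tracts(self) -> int:
        return self.data["tract_id"].nunique()

    @property
    def years(self) -> list[int]:
        return sorted(int(y) for y in self.data["year"].unique())

    @property
    def mileage_variable(self) -> str:
        for v in self.catalog:
            if v.category is VariableCategory.PATH_MILEAGE:
                return v.name
        raise PanelValidationError("panel has no path_mileage variable")

    def category_of(self, name: str) -> VariableCategory:
        for v in self.catalog:
            if v.name == name:
                return v.category
        raise KeyError(name)

    def variables_in(self, categories: Iterable[VariableCategory]) -> list[str]:
        cats = set(categories)
        return [v.name for v in self.catalog if v.category in cats]

    def subset_tracts(self, tracts: Iterable[str]) -> "CityPanel":
        tracts = set(tracts)
        unknown = tracts - set(self.tract_ids)
        if unknown:
            raise KeyError(f"unknown tracts: {sorted(unknown)}")
        mask = self.data["tract_id"].isin(tracts)
        return CityPanel(self.data.loc[mask].copy(), list(self.catalog))

    def subset_years(self, years: Iterable[int]) -> "CityPanel":
        years = set(int(y) for y in years)
        mask = self.data["year"].isin(years)
        if not mask.any():
            raise KeyError(f"panel has no rows in years {sorted(years)}")
        return CityPanel(self.data.loc[mask].copy(), list(self.catalog))

    def rows_for_year(self, year: int) -> pd.DataFrame:
        out = self.data.loc[self.data["year"] == year]
        if out.empty:
            raise KeyError(f"panel has no rows for year {year}")
        return out.set_index("tract_id")

    def value(self, tract_id: str, year: int, variable: str) -> float:
        mask = (self.data["tract_id"] == tract_id) & (self.data["year"] == year)
        sub = self.data.loc[mask, variable]
        if sub.empty:
            raise KeyError(f"no row for tract {tract_id}, year {year}")
        return float(sub.iloc[0])

    def copy(self) -> "CityPanel":
        return CityPanel(self.data.copy(), list(self.catalog))


# -- I/O -----------------------------------------------------------------


def load_catalog(catalog_path) -> list[VariableSpec]:
    """Read a catalog CSV with columns ``name,category,units``."""
    df = pd.read_csv(catalog_path, dtype=str).fillna("")
    for col in ("name", "category"):
        if col not in df.columns:
            raise PanelFormatError(f"catalog is missing mandatory column {col!r}")
    specs = []
    for row in df.itertuples(index=False):
        try:
            cat = VariableCategory(row.category)
        except ValueError as exc:
            raise PanelFormatError(
                f"unknown category {row.category!r} for variable {row.name!r}"
            ) from exc
        specs.append(VariableSpec(row.name, cat, getattr(row, "units", "")))
    return specs


def load_panel(path, catalog_path) -> CityPanel:
    """Read a panel CSV and its catalog, dropping rows with malformed tract IDs.

    The panel CSV must have ``tract_id`` and ``year`` columns plus one column
    per catalog variable.  Rows whose tract ID is not an 11-digit FIPS string
    are dropped and logged rather than failing the whole load.
    """
    catalog = load_catalog(catalog_path)
    df = pd.read_csv(path, dtype={"tract_id": str})
    for col in ID_COLUMNS:
        if col not in df.columns:
            raise PanelFormatError(f"panel CSV is missing mandatory column {col!r}")
    bad = ~df["tract_id"].astype(str).str.match(_FIPS_RE)
    if bad.any():
        for tid in df.loc[bad, "tract_id"].unique():
            logger.warning("dropping rows with malformed tract ID %r", tid)
        df = df.loc[~bad]
    df["year"] = df["year"].astype(int)
    return CityPanel(df, catalog)


def write_panel(panel: CityPanel, path, catalog_path=None) -> None:
    """Write a panel (and optionally its catalog) back to CSV."""
    panel.data.to_csv(path, index=False)
    if catalog_path is not None:
        pd.DataFrame(
            [(v.name, v.category.value, v.units) for v in panel.catalog],
            columns=["name", "category", "units"],
        ).to_csv(catalog_path, index=False)


# -- validation report ----------------------------------------------------


@dataclass(frozen=True)
class Finding:
    """One report-only data-quality observation about a variable."""

    variable: str
    kind: str  # "zero_variance" | "out_of_range" | "missing_values"
    detail: str


def validate_panel(panel: CityPanel) -> list[Finding]:
    """Report-only checks: zero variance, out-of-range prevalences, missingness."""
    findings: list[Finding] = []
    prevalence_vars = set(panel.variables_in(PREVALENCE_CATEGORIES))
    for name in panel.variables:
        col = panel.data[name]
        n_missing = int(col.isna().sum())
        if n_missing:
            frac = n_missing / len(col)
            findings.append(
                Finding(name, "missing_values", f"{frac:.1%} of tract-years missing")
            )
        values = col.dropna()
        if len(values) > 1 and float(values.std()) == 0.0:
            findings.append(Finding(name, "zero_variance", "variable is constant"))
        if name in prevalence_vars:
            out = values[(values < 0) | (values > 100)]
            if len(out):
                findings.append(
                    Finding(
                        name,
                        "out_of_range",
                        f"{len(out)} prevalence values outside [0, 100] "
                        f"(e.g. {float(out.iloc[0])})",
                    )
                )
    return findings


# -- EFA/CFA half split ---------------------------------------------------


@dataclass(frozen=True)
class SplitAssignment:
    """Tract-level partition into an exploratory half and a confirmation half."""

    efa_tracts: frozenset[str]
    cfa_tracts: frozenset[str]

    def __post_init__(self) -> None:
        if self.efa_tracts & self.cfa_tracts:
            raise PanelValidationError("EFA and CFA halves overlap")


def split_halves(panel: CityPanel, seed: int) -> SplitAssignment:
    """Randomly partition tracts, assigning the larger (ceiling) half to EFA.

    All years of a tract land in the same half, so a city with 77 tracts and
    five years of data yields 39 x 5 = 195 exploratory tract-year rows and
    38 x 5 = 190 confirmation rows.
    """
    tracts = panel.tract_ids
    if len(tracts) < 2:
        raise PanelValidationError("need at least 2 tracts to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tracts))
    n_efa = math.ceil(len(tracts) / 2)
    efa = frozenset(tracts[i] for i in order[:n_efa])
    cfa = frozenset(tracts[i] for i in order[n_efa:])
    return SplitAssignment(efa_tracts=efa, cfa_tracts=cfa)


# -- missing-data policy --------------------------------------------------


def clean_missing(
    panel: CityPanel, max_missing_frac: float = 0.20
) -> tuple[CityPanel, list[str]]:
    """Drop heavily missing variables and mean-impute the rest within year.

    Variables missing in more than ``max_missing_frac`` of tract-years are
    dropped with a warning (returned as the second element).  Remaining
    missing cells are imputed with the variable's mean over the same year,
    so that secular trends are not smeared across the panel.
    """
    df = panel.data.copy()
    dropped: list[str] = []
    for name in panel.variables:
        frac = float(df[name].isna().mean())
        if frac > max_missing_frac:
            dropped.append(name)
            logger.warning(
                "dropping variable %r: %.1f%% of tract-years missing", name, 100 * frac
            )
    df = df.drop(columns=dropped)
    keep = [v for v in panel.catalog if v.name not in dropped]
    for name in (v.name for v in keep):
        if df[name].isna().any():
            df[name] = df.groupby("year")[name].transform(lambda s: s.fillna(s.mean()))
    return CityPanel(df, keep), dropped
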