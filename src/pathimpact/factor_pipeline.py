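"""Iterative EFA fit-and-filter, factor labeling, and CFA confirmation.

The pipeline mirrors standard two-sample factor-analysis practice: an
exploratory model is fitted on one random half of a city's tracts, variables
failing the communality rule (absolute pattern loading > 0.5 on the assigned
factor, < 0.5 on every other factor) are discarded and the model refitted
until a clean solution remains; the surviving structure is then refitted as
a confirmatory model on the held-out half and accepted only if the loading
rule still holds and conventional fit indices (CFI, TLI, RMSEA, SRMR) meet
their cutoffs.

Extraction is maximum-likelihood (sklearn's EM factor analysis) on the
z-standardized fitting half; rotation is oblique quartimin via the gradient
projection algorithm, since the three substantive factors (demographics,
health burden, path habits) are expected to correlate.  The confirmatory
model is a congeneric simple-structure ML fit (free loadings on the assigned
factor only, free factor correlations, unit factor variances) optimised with
L-BFGS-B on the ML discrepancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.decomposition import FactorAnalysis

from .city_panel import (
    BPH_CATEGORIES,
    CityPanel,
    DBC_CATEGORIES,
    HEALTH_CATEGORIES,
    VariableCategory,
    VariableSpec,
    clean_missing,
)

logger = logging.getLogger("pathimpact")

#: Absolute pattern-loading rule from the model-assessment stage.
LOADING_THRESHOLD = 0.5

FACTOR_LABELS = ("DBC", "health", "BPH")


class RequirementsUnmetError(RuntimeError):
    """No admissible factor model exists for this candidate set."""


class EstimationError(RuntimeError):
    """Numerical failure while fitting a factor model."""


@dataclass
class FitIndexCutoffs:
    """Conventional goodness-of-fit cutoffs for confirming a model."""

    cfi: float = 0.90
    tli: float = 0.90
    rmsea: float = 0.08
    srmr: float = 0.08

    def passes(self, indices: dict[str, float]) -> bool:
        return (
            indices["CFI"] >= self.cfi
            and indices["TLI"] >= self.tli
            and indices["RMSEA"] <= self.rmsea
            and indices["SRMR"] <= self.srmr
        )


@dataclass
class FactorModel:
    """A fitted (and possibly confirmed) factor model.

    ``loadings`` is the oblique pattern matrix over ``retained_vars``;
    ``assignment`` maps each retained variable to its argmax-|loading|
    factor index; ``labels`` maps factor index to one of DBC/health/BPH (or
    ``other``); ``scoring_weights`` are regression (Thurstone) weights
    mapping z-standardized observed variables to raw factor scores; the two
    standardization blocks freeze the fitting sample's variable means/SDs
    and raw-score means/SDs so that a modified tract can be rescored without
    refitting anything.
    """

    retained_vars: list[str]
    n_factors: int
    loadings: np.ndarray  # (p, m) pattern matrix
    assignment: dict[str, int]
    factor_correlations: np.ndarray  # (m, m)
    scoring_weights: np.ndarray  # (p, m)
    var_means: np.ndarray  # (p,)
    var_sds: np.ndarray  # (p,)
    score_means: np.ndarray  # (m,)
    score_sds: np.ndarray  # (m,)
    labels: dict[int, str] = field(default_factory=dict)
    catalog: list[VariableSpec] = field(default_factory=list)

    # -- label helpers ----------------------------------------------------

    def factor_index(self, label: str) -> int:
        for idx, lab in self.labels.items():
            if lab == label:
                return idx
        raise KeyError(f"model has no factor labeled {label!r}")

    @property
    def label_names(self) -> list[str]:
        return [self.labels.get(j, f"factor_{j}") for j in range(self.n_factors)]

    def variables_of_factor(self, idx: int) -> list[str]:
        return [v for v in self.retained_vars if self.assignment[v] == idx]

    def health_outcome_variables(self) -> list[str]:
        """CDC health-outcome variables assigned to the health factor."""
        idx = self.factor_index("health")
        cats = {v.name: v.category for v in self.catalog}
        return [
            v
            for v in self.variables_of_factor(idx)
            if cats.get(v) is VariableCategory.CDC_HEALTH_OUTCOME
        ]

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "retained_vars": self.retained_vars,
            "n_factors": self.n_factors,
            "loadings": self.loadings.tolist(),
            "assignment": self.assignment,
            "factor_correlations": self.factor_correlations.tolist(),
            "scoring_weights": self.scoring_weights.tolist(),
            "var_means": self.var_means.tolist(),
            "var_sds": self.var_sds.tolist(),
            "score_means": self.score_means.tolist(),
            "score_sds": self.score_sds.tolist(),
            "labels": {str(k): v for k, v in self.labels.items()},
            "catalog": [
                {"name": v.name, "category": v.category.value, "units": v.units}
                for v in self.catalog
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FactorModel":
        return cls(
            retained_vars=list(d["retained_vars"]),
            n_factors=int(d["n_factors"]),
            loadings=np.asarray(d["loadings"], dtype=float),
            assignment={k: int(v) for k, v in d["assignment"].items()},
            factor_correlations=np.asarray(d["factor_correlations"], dtype=float),
            scoring_weights=np.asarray(d["scoring_weights"], dtype=float),
            var_means=np.asarray(d["var_means"], dtype=float),
            var_sds=np.asarray(d["var_sds"], dtype=float),
            score_means=np.asarray(d["score_means"], dtype=float),
            score_sds=np.asarray(d["score_sds"], dtype=float),
            labels={int(k): v for k, v in d["labels"].items()},
            catalog=[
                VariableSpec(c["name"], VariableCategory(c["category"]), c["units"])
                for c in d["catalog"]
            ],
        )


@dataclass
class FitReport:
    """Diagnostics from one EFA or CFA fit."""

    iterations: int
    discarded: list[tuple[str, int, str]]  # (variable, iteration, reason)
    fit_indices: dict[str, float]
    confirmed: bool = False
    degenerate: bool = False


# -- matrix preparation ----------------------------------------------------


def _design_matrix(
    panel: CityPanel, variables: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Pooled tract-year matrix for the given variables, missing cells imputed."""
    cleaned, dropped = clean_missing(panel)
    kept = [v for v in variables if v not in dropped]
    X = cleaned.data[kept].to_numpy(dtype=float)
    return X, kept

def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise EstimationError("zero-variance variable in the fitting sample")
    return (X - means) / sds, means, sds


# -- oblique rotation ------------------------------------------------------


def _quartimin(L: np.ndarray) -> tuple[float, np.ndarray]:
    """Quartimin criterion value and gradient wrt the rotated loadings."""
    L2 = L**2
    m = L.shape[1]
    N = np.ones((m, m)) - np.eye(m)
    X = L2 @ N
    f = float((L2 * X).sum()) / 4.0
    return f, L * X


def rotate_quartimin(
    A: np.ndarray, max_iter: int = 500, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Oblique quartimin rotation by gradient projection.

    Returns the rotated pattern matrix and the factor correlation matrix.
    Follows the oblique gradient-projection iteration of Jennrich/Bernaards:
    columns of the rotation matrix are kept unit-length, and the step is
    halved until the criterion decreases.
    """
    p, m = A.shape
    if m == 1:
        return A.copy(), np.ones((1, 1))
    T = np.eye(m)
    L = A @ np.linalg.inv(T).T
    f, Gq = _quartimin(L)
    G = -(L.T @ Gq @ np.linalg.inv(T)).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0)
        s = float(np.linalg.norm(Gp))
        if s < tol:
            break
        al *= 2.0
        for _ in range(50):
            X = T - al * Gp
            X = X / np.sqrt((X**2).sum(axis=0))
            try:
                Xi = np.linalg.inv(X)
            except np.linalg.LinAlgError:
                al /= 2.0
                continue
            Lt = A @ Xi.T
            ft, Gqt = _quartimin(Lt)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        else:
            break
        T, L, f, Gq = X, Lt, ft, Gqt
        G = -(L.T @ Gq @ np.linalg.inv(T)).T
    Phi = T.T @ T
    # sign convention: each factor's dominant loadings positive
    signs = np.sign(L.sum(axis=0))
    signs[signs == 0] = 1.0
    L = L * signs
    Phi = Phi * np.outer(signs, signs)
    return L, Phi


# -- ML extraction ---------------------------------------------------------


def _extract_ml(Z: np.ndarray, m: int, seed: int) -> np.ndarray:
    """Unrotated ML loadings (p, m) on the correlation metric."""
    fa = FactorAnalysis(
        n_components=m,
        svd_method="lapack",
        max_iter=5000,
        tol=1e-4,
        random_state=seed,
    )
    try:
        fa.fit(Z)
    except Exception as exc:  # pragma: no cover - sklearn numeric failure
        raise EstimationError(f"EFA extraction failed: {exc}") from exc
    A = fa.components_.T
    if not np.all(np.isfinite(A)):
        raise EstimationError("EFA extraction produced non-finite loadings")
    return A


# -- fit indices -----------------------------------------------------------


def _ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    p = S.shape[0]
    sign, logdet_sigma = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet_sigma + np.trace(S @ np.linalg.inv(Sigma)) - logdet_s - p)


def _fit_indices(
    S: np.ndarray, Sigma: np.ndarray, n_obs: int, df: int
) -> dict[str, float]:
    """CFI, TLI, RMSEA, SRMR of a fitted covariance structure."""
    p = S.shape[0]
    F = _ml_discrepancy(S, Sigma)
    chi2 = (n_obs - 1) * F
    # independence baseline on the correlation metric
    F_base = _ml_discrepancy(S, np.diag(np.diag(S)))
    chi2_base = (n_obs - 1) * F_base
    df_base = p * (p - 1) // 2
    num = max(chi2 - df, 0.0)
    den = max(chi2_base - df_base, chi2 - df, 1e-12)
    cfi = 1.0 - num / den
    if df > 0 and df_base > 0 and chi2_base / df_base > 1:
        tli = ((chi2_base / df_base) - (chi2 / df)) / ((chi2_base / df_base) - 1.0)
    else:
        tli = 1.0
    tli = min(tli, 1.0)
    rmsea = np.sqrt(max(chi2 - df, 0.0) / (df * (n_obs - 1))) if df > 0 else 0.0
    resid = S - Sigma
    iu = np.triu_indices(p)
    srmr = float(np.sqrt((resid[iu] ** 2).mean()))
    return {
        "CFI": float(cfi),
        "TLI": float(tli),
        "RMSEA": float(rmsea),
        "SRMR": srmr,
        "chi2": float(chi2),
        "df": float(df),
    }


# -- iterative EFA ---------------------------------------------------------


def _violations(
    L: np.ndarray, R: np.ndarray, variables: Sequence[str], threshold: float
) -> list[tuple[str, str]]:
    """Variables breaking the communality rule, with a human-readable reason.

    A variable's communality with a factor is the variance it shares with
    the other variables grouped in that factor — the mean squared sample
    correlation with them, which is invariant to the rotation's freedom to
    tilt factors toward a straddling variable.  A retained variable must
    share more than ``threshold`` variance with its assigned factor's
    variables and less than ``threshold`` with every other factor's; on top
    of that, simple structure is enforced on the rotated pattern matrix
    (assigned |pattern| above 0.5, cross |pattern| below 0.5).
    """
    m = L.shape[1]
    assign = np.argmax(np.abs(L), axis=1)
    groups = [np.flatnonzero(assign == j) for j in range(m)]
    R2 = R**2
    out = []
    for i, name in enumerate(variables):
        j = int(assign[i])
        own = [k for k in groups[j] if k != i]
        own_comm = float(R2[i, own].mean()) if own else 0.0
        if own_comm <= threshold:
            out.append(
                (name, f"shares only {own_comm:.2f} variance with its factor")
            )
            continue
        cross = [
            (g, float(R2[i, groups[g]].mean()))
            for g in range(m)
            if g != j and len(groups[g])
        ]
        bad_cross = [(g, c) for g, c in cross if c >= threshold]
        if bad_cross:
            g, c = max(bad_cross, key=lambda t: t[1])
            out.append((name, f"shares {c:.2f} variance with factor {g}"))
            continue
        pat = np.abs(L[i])
        if pat[j] <= 0.5:
            out.append((name, f"primary pattern loading {pat[j]:.3f} <= 0.5"))
            continue
        off_pat = np.delete(pat, j)
        if off_pat.size and off_pat.max() >= 0.5:
            out.append((name, f"cross pattern loading {off_pat.max():.3f} >= 0.5"))
    return out


def _build_model(
    variables: list[str],
    L: np.ndarray,
    Phi: np.ndarray,
    Z: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
    catalog: list[VariableSpec],
) -> FactorModel:
    """Assemble a FactorModel with regression scoring weights.

    Thurstone weights W = R^{-1} (Lambda Phi) applied to z-scores; the raw
    scores' mean/SD on the fitting sample are stored so scores can be
    standardized identically for any later tract.
    """
    R = np.corrcoef(Z, rowvar=False)
    structure = L @ Phi
    try:
        W = np.linalg.solve(R, structure)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("singular correlation matrix in scoring") from exc
    raw = Z @ W
    score_means = raw.mean(axis=0)
    score_sds = raw.std(axis=0, ddof=1)
    if np.any(score_sds == 0):
        raise EstimationError("degenerate factor scores (zero variance)")
    assignment = {v: int(np.argmax(np.abs(L[i]))) for i, v in enumerate(variables)}
    kept_cats = {v.name: v for v in catalog}
    return FactorModel(
        retained_vars=list(variables),
        n_factors=L.shape[1],
        loadings=L.copy(),
        assignment=assignment,
        factor_correlations=Phi.copy(),
        scoring_weights=W,
        var_means=means.copy(),
        var_sds=sds.copy(),
        score_means=score_means,
        score_sds=score_sds,
        catalog=[kept_cats[v] for v in variables],
    )


def run_efa(
    panel_half: CityPanel,
    candidate_vars: Sequence[str] | None = None,
    max_factors: int = 6,
    seed: int = 0,
    threshold: float = LOADING_THRESHOLD,
) -> tuple[FactorModel, FitReport]:
    """Iterative exploratory fit on the EFA half.

    For each candidate factor count m = 3..max_factors (smallest first), the
    model is fitted with oblique quartimin rotation, every variable violating
    the 0.5 loading rule is discarded, and the fit repeats on the survivors
    until no violations remain.  The first m whose clean solution keeps at
    least three variables on every factor wins.  Because each m restarts from
    the full candidate pool, variables discarded under a factor count whose
    solution collapsed re-enter the search automatically.

    Raises
    ------
    RequirementsUnmetError
        If no factor count in the range admits a clean three-per-factor
        solution (e.g. pure-noise data).
    """
    if candidate_vars is None:
        candidate_vars = panel_half.variables
    candidate_vars = list(candidate_vars)

    cats = {v.name: v.category for v in panel_half.catalog}
    if not any(cats.get(v) is VariableCategory.PATH_MILEAGE for v in candidate_vars):
        raise ValueError("candidate set must include the path-mileage variable")
    if not any(
        cats.get(v) is VariableCategory.CDC_HEALTH_OUTCOME for v in candidate_vars
    ):
        raise ValueError("candidate set must include at least one health outcome")

    X_all, kept_vars = _design_matrix(panel_half, candidate_vars)
    n_rows = X_all.shape[0]
    if n_rows < 5 * len(kept_vars):
        raise ValueError(
            f"too few tract-year rows ({n_rows}) for {len(kept_vars)} candidate "
            "variables; need at least 5 rows per variable"
        )
    col_of = {v: i for i, v in enumerate(kept_vars)}

    last_error: str | None = None
    for m in range(3, max_factors + 1):
        variables = list(kept_vars)
        discarded: list[tuple[str, int, str]] = []
        iteration = 0
        while True:
            iteration += 1
            if len(variables) < 3 * m:
                last_error = (
                    f"m={m}: only {len(variables)} variables left, need {3 * m}"
                )
                break
            X = X_all[:, [col_of[v] for v in variables]]
            try:
                Z, means, sds = _standardize(X)
                A = _extract_ml(Z, m, seed)
                L, Phi = rotate_quartimin(A)
            except EstimationError as exc:
                last_error = f"m={m}: {exc}"
                break
            bad = _violations(L, np.corrcoef(Z, rowvar=False), variables, threshold)
            if bad:
                for name, reason in bad:
                    discarded.append((name, iteration, reason))
                    logger.info("EFA iteration %d: discarding %s (%s)", iteration, name, reason)
                variables = [v for v in variables if v not in {n for n, _ in bad}]
                continue
            # clean solution: demand >= 3 variables on every factor
            counts = np.bincount(
                [int(np.argmax(np.abs(L[i]))) for i in range(len(variables))],
                minlength=m,
            )
            if counts.min() < 3:
                last_error = f"m={m}: a factor retained only {counts.min()} variables"
                break
            model = _build_model(
                variables, L, Phi, Z, means, sds, panel_half.catalog
            )
            Psi = np.clip(1.0 - np.diag(L @ Phi @ L.T), 1e-6, None)
            Sigma = L @ Phi @ L.T + np.diag(Psi)
            p = len(variables)
            df = max(((p - m) ** 2 - (p + m)) // 2, 1)
            indices = _fit_indices(np.corrcoef(Z, rowvar=False), Sigma, n_rows, df)
            report = FitReport(
                iterations=iteration, discarded=discarded, fit_indices=indices
            )
            return model, report
    raise RequirementsUnmetError(
        "no admissible factor model in the searched range"
        + (f" (last: {last_error})" if last_error else "")
    )


# -- factor labeling -------------------------------------------------------


_GROUPS = {
    "DBC": DBC_CATEGORIES,
    "health": HEALTH_CATEGORIES,
    "BPH": BPH_CATEGORIES,
}


def label_factors(model: FactorModel, catalog: Sequence[VariableSpec]) -> FactorModel:
    """Label each factor DBC / health / BPH by its majority category group.

    Ties (and duplicate claims on a label) are broken by the larger mean
    absolute loading of the group's variables on the factor.  The labeled
    model must contain all three substantive factors, the health factor must
    include a health-outcome variable, and the BPH factor must include the
    path-mileage variable; otherwise the model fails the structural
    requirements of the method.
    """
    cats = {v.name: v.category for v in catalog}
    missing = [v for v in model.retained_vars if v not in cats]
    if missing:
        raise KeyError(f"catalog lacks retained variables: {missing}")

    # score each (factor, label) pair: majority count, then mean |loading|
    claims: dict[str, list[tuple[int, float, int]]] = {g: [] for g in _GROUPS}
    for j in range(model.n_factors):
        members = model.variables_of_factor(j)
        if not members:
            continue
        rows = {v: model.loadings[model.retained_vars.index(v), j] for v in members}
        best_label, best_key = None, None
        for label, group in _GROUPS.items():
            in_group = [v for v in members if cats[v] in group]
            if not in_group:
                continue
            key = (
                len(in_group),
                float(np.mean([abs(rows[v]) for v in in_group])),
            )
            if best_key is None or key > best_key:
                best_label, best_key = label, key
        if best_label is not None:
            claims[best_label].append((j, best_key[1], best_key[0]))

    labels: dict[int, str] = {}
    for label, claimants in claims.items():
        if not claimants:
            continue
        # duplicate claims: factor with most group members, then mean |loading|
        j = max(claimants, key=lambda c: (c[2], c[1]))[0]
        labels[j] = label
    for j in range(model.n_factors):
        labels.setdefault(j, "other")

    present = set(labels.values())
    absent = [g for g in _GROUPS if g not in present]
    if absent:
        raise RequirementsUnmetError(
            f"requirements unmet: no factor qualifies as {', '.join(absent)}"
        )
    health_members = model.variables_of_factor(
        next(j for j, l in labels.items() if l == "health")
    )
    if not any(cats[v] is VariableCategory.CDC_HEALTH_OUTCOME for v in health_members):
        raise RequirementsUnmetError(
            "requirements unmet: health factor has no health-outcome variable"
        )
    bph_members = model.variables_of_factor(
        next(j for j, l in labels.items() if l == "BPH")
    )
    if not any(cats[v] is VariableCategory.PATH_MILEAGE for v in bph_members):
        raise RequirementsUnmetError(
            "requirements unmet: BPH factor lacks the path-mileage variable"
        )
    return replace(model, labels=labels)


# -- confirmatory fit ------------------------------------------------------


def _cfa_sigma(
    lam: np.ndarray, psi: np.ndarray, phi_l: np.ndarray, assign_idx: np.ndarray, m: int
) -> np.ndarray:
    p = lam.shape[0]
    Lam = np.zeros((p, m))
    Lam[np.arange(p), assign_idx] = lam
    Phi = np.eye(m)
    iu = np.triu_indices(m, k=1)
    Phi[iu] = phi_l
    Phi[(iu[1], iu[0])] = phi_l
    return Lam @ Phi @ Lam.T + np.diag(psi), Lam, Phi


def run_cfa(
    model: FactorModel,
    panel_half: CityPanel,
    cutoffs: FitIndexCutoffs | None = None,
    threshold: float = LOADING_THRESHOLD,
) -> FitReport:
    """Confirm the hypothesized structure on the held-out half.

    Refits loadings with the variable->factor assignment fixed (a congeneric
    simple-structure ML model: one free loading per variable, free factor
    correlations, unit factor variances).  The model is confirmed when every
    refitted loading passes the 0.5 rule — including structure cross-loadings
    |Lambda Phi| staying below 0.5 — and the fit indices meet the cutoffs.
    On confirmation the model's loadings, factor correlations, scoring
    weights and standardization constants are updated in place to the
    confirmation-half estimates.
    """
    cutoffs = cutoffs or FitIndexCutoffs()
    X, kept = _design_matrix(panel_half, model.retained_vars)
    if kept != model.retained_vars:
        missing = set(model.retained_vars) - set(kept)
        raise EstimationError(f"confirmation half lacks usable variables: {missing}")
    Z, means, sds = _standardize(X)
    R = np.corrcoef(Z, rowvar=False)
    n_obs, p = Z.shape
    m = model.n_factors
    assign_idx = np.array([model.assignment[v] for v in model.retained_vars])

    # starting values from the exploratory solution
    lam0 = np.array(
        [model.loadings[i, assign_idx[i]] for i in range(p)], dtype=float
    )
    psi0 = np.clip(1.0 - lam0**2, 0.05, 0.95)
    iu = np.triu_indices(m, k=1)
    phi0 = model.factor_correlations[iu]

    def unpack(theta):
        return theta[:p], theta[p : 2 * p], theta[2 * p :]

    def objective(theta):
        lam, psi, phi_l = unpack(theta)
        Sigma, _, Phi = _cfa_sigma(lam, psi, phi_l, assign_idx, m)
        if np.linalg.eigvalsh(Phi).min() <= 1e-8:
            return 1e6
        F = _ml_discrepancy(R, Sigma)
        return F if np.isfinite(F) else 1e6

    theta0 = np.concatenate([lam0, psi0, phi0])
    bounds = (
        [(-2.0, 2.0)] * p + [(1e-3, 2.0)] * p + [(-0.98, 0.98)] * (m * (m - 1) // 2)
    )
    res = optimize.minimize(
        objective, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-12},
    )
    if not np.all(np.isfinite(res.x)):
        raise EstimationError(f"CFA estimation failed: {res.message}")
    lam, psi, phi_l = unpack(res.x)
    Sigma, Lam, Phi = _cfa_sigma(lam, psi, phi_l, assign_idx, m)

    n_params = 2 * p + m * (m - 1) // 2
    df = p * (p + 1) // 2 - n_params
    indices = _fit_indices(R, Sigma, n_obs, max(df, 1))

    # loading rule on the confirmation sample: every variable's single free
    # loading must clear the threshold (cross-loadings are structurally zero
    # in the simple-structure model)
    ok = all(abs(Lam[i, assign_idx[i]]) > threshold for i in range(p))
    confirmed = bool(ok and cutoffs.passes(indices))

    if confirmed:
        model.loadings = Lam
        model.factor_correlations = Phi
        try:
            W = np.linalg.solve(R, Lam @ Phi)
        except np.linalg.LinAlgError as exc:
            raise EstimationError("singular correlation matrix in CFA scoring") from exc
        raw = Z @ W
        model.scoring_weights = W
        model.var_means = means
        model.var_sds = sds
        model.score_means = raw.mean(axis=0)
        model.score_sds = raw.std(axis=0, ddof=1)

    return FitReport(
        iterations=1,
        discarded=[],
        fit_indices=indices,
        confirmed=confirmed,
        degenerate=not res.success,
    )
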