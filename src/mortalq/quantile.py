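"""Weighted quantile regression of FI trajectories.

Marginal (population-averaged) quantile regression under an independence
working assumption: the point estimator pools all observed person-waves and
minimizes the weighted check loss

    sum_i w_i * rho_tau(y_i - x_i' beta),    rho_tau(u) = u * (tau - 1{u < 0}),

treating within-person observations as uncorrelated; within-person
correlation is handled in the variance step by the cluster bootstrap (see
:mod:`mortalq.inference`). The default solver is the exact linear-programming
formulation (minimize tau * w'u+ + (1-tau) * w'u- subject to
X beta + u+ - u- = y, u+/- >= 0) via HiGHS; a smoothed iteratively
reweighted least-squares fallback is available.

Two model formulas are supported for the FI trajectory: the base model with
sex, education, baseline age, age, and age interactions, and the cohort model
adding a born-1946-or-later indicator and its age interaction. Age and
baseline age are centered at 65 years; education at the analysis-sample mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import qr as _qr
from scipy.optimize import linprog
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import ConfigurationError, DataError, SolverError

__all__ = [
    "FORMULA_TERMS",
    "build_design",
    "QuantileRegressor",
    "QuantileFit",
    "fit_wqr",
    "fit_quantile_model",
    "fit_all",
    "check_loss",
    "subgradient_bracket",
]

#: Design terms per model formula, in column order (intercept excluded;
#: the estimator adds it).
FORMULA_TERMS: dict[str, tuple[str, ...]] = {
    "intercept": (),
    "base": (
        "sex",
        "educ",
        "base_age",
        "age",
        "age_sex",
        "age_educ",
        "age_base_age",
    ),
    "cohort": (
        "sex",
        "educ",
        "base_age",
        "cohort",
        "age",
        "age_sex",
        "age_educ",
        "age_base_age",
        "age_cohort",
    ),
}

AGE_CENTER = 65.0


def check_loss(u: np.ndarray, tau: float, weights: np.ndarray | None = None) -> float:
    """Weighted check (pinball) loss ``sum w * u * (tau - 1{u<0})``."""
    u = np.asarray(u, float)
    rho = u * (tau - (u < 0))
    if weights is None:
        return float(rho.sum())
    return float(np.asarray(weights, float) @ rho)


def build_design(
    panel: pd.DataFrame,
    formula: str = "base",
    educ_center: float | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, dict]:
    """Build the trajectory design matrix from an analysis panel.

    Restricts to rows with an observed FI, centers age and baseline age at
    65 and education at the analysis-sample mean (or ``educ_center`` when
    given, e.g. inside a prediction path that must reuse the fit's own
    centering), and forms interaction columns as products of centered mains.

    Returns ``(X, y, row_index, centering)`` where ``X`` has the columns of
    :data:`FORMULA_TERMS[formula]` (no intercept column), ``y`` is the FI,
    ``row_index`` maps design rows back to (id, wave), and ``centering``
    records the constants used.
    """
    if formula not in FORMULA_TERMS:
        raise ConfigurationError(
            f"formula must be one of {sorted(FORMULA_TERMS)}, got {formula!r}"
        )
    rows = panel.loc[panel["fi"].notna()].copy()
    if rows.empty:
        raise DataError("panel has no rows with observed FI")
    if formula == "intercept":
        X = pd.DataFrame(index=rows.index)
        y = rows["fi"].rename("fi")
        return X, y, rows[["id", "wave"]].copy(), {"age_center": AGE_CENTER}
    needed = ["sex", "educ_years", "base_age", "age"]
    if formula == "cohort":
        needed.append("born_1946plus")
    bad = rows[needed].isna().any(axis=1)
    if bad.any():
        raise DataError(
            "missing covariates on observed rows: "
            f"{rows.loc[bad, ['id', 'wave']].to_records(index=False).tolist()[:10]}"
        )
    if educ_center is None:
        educ_center = float(rows["educ_years"].mean())
    age_c = rows["age"] - AGE_CENTER
    educ_c = rows["educ_years"] - educ_center
    ba_c = rows["base_age"] - AGE_CENTER
    cols = {
        "sex": rows["sex"].astype(float),
        "educ": educ_c,
        "base_age": ba_c,
        "age": age_c,
        "age_sex": age_c * rows["sex"],
        "age_educ": age_c * educ_c,
        "age_base_age": age_c * ba_c,
    }
    if formula == "cohort":
        boom = rows["born_1946plus"].astype(float)
        cols["cohort"] = boom
        cols["age_cohort"] = age_c * boom
    X = pd.DataFrame({t: cols[t] for t in FORMULA_TERMS[formula]})
    X.index = rows.index
    y = rows["fi"].rename("fi")
    row_index = rows[["id", "wave"]].copy()
    centering = {"educ_center": educ_center, "age_center": AGE_CENTER}
    return X, y, row_index, centering


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Names of columns not in a pivoted-QR column basis (rank deficiency)."""
    r = np.linalg.matrix_rank(X)
    if r == X.shape[1]:
        return []
    _, _, piv = _qr(X, pivoting=True, mode="economic")
    dependent = sorted(piv[r:])
    return [names[j] for j in dependent]


class QuantileRegressor(RegressorMixin, BaseEstimator):
    """Linear quantile regression by weighted check-loss minimization.

    Sklearn-style estimator: ``fit(X, y, sample_weight)`` minimizes
    ``sum_i w_i rho_tau(y_i - x_i' beta)`` and exposes ``intercept_`` and
    ``coef_``. The default solver is the exact LP formulation solved with
    HiGHS, which returns a vertex of the (possibly degenerate) solution set;
    in degenerate instances the minimizer is an interval and only the loss is
    unique. ``solver="irls"`` smooths the check loss (|u| ~ sqrt(u^2 + eps))
    and iterates reweighted least squares — faster on very large dense
    problems but approximate near the kink.

    Parameters
    ----------
    tau : float in (0, 1)
        The quantile level.
    fit_intercept : bool, default True
    solver : {"lp", "irls"}
    irls_tol, irls_max_iter, irls_eps : IRLS fallback controls.

    Attributes
    ----------
    coef_ : ndarray of shape (p,)
    intercept_ : float
    loss_ : float
        Weighted check loss at the solution.
    solver_status_ : str
    n_obs_ : int
    """

    def __init__(
        self,
        tau: float = 0.5,
        fit_intercept: bool = True,
        solver: str = "lp",
        irls_tol: float = 1e-10,
        irls_max_iter: int = 200,
        irls_eps: float = 1e-8,
    ):
        self.tau = tau
        self.fit_intercept = fit_intercept
        self.solver = solver
        self.irls_tol = irls_tol
        self.irls_max_iter = irls_max_iter
        self.irls_eps = irls_eps

    def _validate(self, X, y, sample_weight):
        if not 0.0 < self.tau < 1.0:
            raise ConfigurationError("tau must be in (0, 1)")
        if self.solver not in ("lp", "irls"):
            raise ConfigurationError(f"unknown solver {self.solver!r}")
        names = (
            list(X.columns)
            if isinstance(X, pd.DataFrame)
            else [f"x{j}" for j in range(np.asarray(X).shape[1])]
        )
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise DataError("X and y have incompatible shapes")
        if sample_weight is None:
            w = np.ones(len(y))
        else:
            w = np.asarray(sample_weight, float)
            if w.shape != y.shape:
                raise DataError("sample_weight misaligned with y")
            if np.any(w <= 0) or not np.all(np.isfinite(w)):
                raise DataError("sample weights must be positive and finite")
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(y)), X])
            names = ["intercept"] + names
        collinear = _collinear_columns(X, names)
        if collinear:
            raise DataError(f"design matrix is rank deficient: {collinear}")
        return X, y, w, names

    def fit(self, X, y, sample_weight=None):
        Xa, ya, w, names = self._validate(X, y, sample_weight)
        if self.solver == "lp":
            beta, status = self._fit_lp(Xa, ya, w)
        else:
            beta, status = self._fit_irls(Xa, ya, w)
        self.solver_status_ = status
        self.loss_ = check_loss(ya - Xa @ beta, self.tau, w)
        self.n_obs_ = len(ya)
        self.feature_names_in_ = np.asarray(
            names[1:] if self.fit_intercept else names, dtype=object
        )
        self.n_features_in_ = len(self.feature_names_in_)
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        return self

    def _fit_lp(self, X, y, w):
        # Dual LP of weighted QR: max_a sum_i w_i y_i a_i subject to
        # X' diag(w) a = 0 and a_i in [tau-1, tau]. The primal coefficients
        # are the (negated) marginals of the p equality constraints, and the
        # optimum equals the primal check loss. Far fewer constraints than
        # the primal (p vs n), so HiGHS solves it much faster at equal
        # exactness.
        n, p = X.shape
        c = -(w * y)
        A_eq = (X * w[:, None]).T
        res = linprog(
            c,
            A_eq=A_eq,
            b_eq=np.zeros(p),
            bounds=[(self.tau - 1.0, self.tau)] * n,
            method="highs",
        )
        if not res.success:
            raise SolverError(
                f"LP solver failed (status {res.status}): {res.message}"
            )
        return -np.asarray(res.eqlin.marginals, float), f"highs:{res.status}"

    def _fit_irls(self, X, y, w):
        # Smoothed check loss: rho_tau(u) ~ u*(tau - 1/2) + sqrt(u^2+eps)/2,
        # minimized by iteratively reweighted least squares.
        eps = self.irls_eps
        beta = np.linalg.lstsq(X * np.sqrt(w)[:, None], y * np.sqrt(w), rcond=None)[0]
        for it in range(self.irls_max_iter):
            u = y - X @ beta
            # stationarity: X'[w(tau-1/2) + W u] = 0 with W = w/(2 sqrt(u^2+eps))
            W = w / (2.0 * np.sqrt(u**2 + eps))
            A = X.T @ (W[:, None] * X)
            b = X.T @ (W * y) + X.T @ (w * (self.tau - 0.5))
            new_beta = np.linalg.solve(A, b)
            if np.max(np.abs(new_beta - beta)) < self.irls_tol:
                beta = new_beta
                return beta, f"irls:converged:{it + 1}"
            beta = new_beta
        return beta, f"irls:maxiter:{self.irls_max_iter}"

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, float)
        return self.intercept_ + X @ self.coef_


def subgradient_bracket(
    X, y, beta_full: np.ndarray, tau: float, weights=None, tol: float = 1e-8
) -> tuple[float, float]:
    """Weighted residual-sign fractions around a candidate solution.

    Returns ``(frac_negative, frac_nonpositive)`` where the fractions weight
    rows by their sample weight. At a check-loss optimum these bracket tau:
    frac_negative <= tau <= frac_nonpositive (up to the weight mass sitting
    exactly on zero residuals).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.shape[1] == len(beta_full) - 1:
        X = np.column_stack([np.ones(len(y)), X])
    u = y - X @ beta_full
    w = np.ones(len(y)) if weights is None else np.asarray(weights, float)
    total = w.sum()
    return float(w[u < -tol].sum() / total), float(w[u <= tol].sum() / total)


@dataclass
class QuantileFit:
    """A fitted quantile-trajectory model.

    Holds everything prediction needs: the quantile level, the formula, the
    named coefficients (intercept first), and the centering constants used to
    build the design, so curves on the raw age axis are unambiguous.
    """

    tau: float
    formula: str
    terms: tuple[str, ...]
    coef: pd.Series  # index: ("intercept",) + terms
    loss: float
    n_obs: int
    solver_status: str
    centering: dict = field(default_factory=dict)

    @property
    def params(self) -> pd.Series:
        return self.coef

    def __getitem__(self, term: str) -> float:
        return float(self.coef[term])


def fit_wqr(
    X,
    y,
    weights=None,
    tau: float = 0.5,
    solver: str = "lp",
    formula: str = "custom",
    centering: dict | None = None,
) -> QuantileFit:
    """Fit one weighted quantile regression and wrap it as a QuantileFit."""
    reg = QuantileRegressor(tau=tau, solver=solver).fit(X, y, sample_weight=weights)
    names = ["intercept"] + list(reg.feature_names_in_)
    coef = pd.Series(
        np.concatenate([[reg.intercept_], reg.coef_]), index=names, name=f"tau_{tau:g}"
    )
    frac_neg, frac_nonpos = subgradient_bracket(
        X, y, coef.to_numpy(), tau, weights
    )
    fit = QuantileFit(
        tau=tau,
        formula=formula,
        terms=tuple(reg.feature_names_in_),
        coef=coef,
        loss=reg.loss_,
        n_obs=reg.n_obs_,
        solver_status=reg.solver_status_,
        centering=dict(centering or {}),
    )
    fit.subgradient = (frac_neg, frac_nonpos)
    return fit


def fit_quantile_model(
    panel: pd.DataFrame,
    tau: float,
    formula: str = "base",
    weights: pd.Series | Mapping | None = None,
    solver: str = "lp",
) -> QuantileFit:
    """Fit the FI-trajectory quantile model on an analysis panel.

    ``weights`` maps (id, wave) to a stabilized weight (a Series indexed that
    way, or a WeightTable DataFrame with id/wave/weight columns); omitted or
    None means the unweighted procedure (all weights 1).
    """
    X, y, row_index, centering = build_design(panel, formula)
    w = _align_weights(weights, row_index)
    return fit_wqr(
        X, y, weights=w, tau=tau, solver=solver, formula=formula, centering=centering
    )


def _align_weights(weights, row_index: pd.DataFrame) -> np.ndarray | None:
    if weights is None:
        return None
    if isinstance(weights, pd.DataFrame):
        weights = weights.set_index(["id", "wave"])["weight"]
    key = pd.MultiIndex.from_frame(row_index[["id", "wave"]])
    aligned = pd.Series(weights).reindex(key)
    if aligned.isna().any():
        missing = key[aligned.isna()][:5].tolist()
        raise DataError(f"no weight for observed rows, e.g. {missing}")
    return aligned.to_numpy(float)


def fit_all(
    panel: pd.DataFrame,
    weights=None,
    formula: str = "base",
    taus: Sequence[float] = (0.1, 0.5, 0.9),
    solver: str = "lp",
) -> dict[float, QuantileFit]:
    """Fit the model independently at each tau on identical design/weights."""
    X, y, row_index, centering = build_design(panel, formula)
    w = _align_weights(weights, row_index)
    return {
        tau: fit_wqr(
            X, y, weights=w, tau=tau, solver=solver,
            formula=formula, centering=centering,
        )
        for tau in taus
    }
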