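"""Stabilized inverse-probability-of-observation weights.

In a mortal cohort with intermittent missingness, pooled quantile regression
on the observed person-waves is biased when the probability of being
interviewed depends on frailty history. Under the unconditional
missing-at-random assumption — observation may depend on recorded history but
not on survival time — consistency is restored by weighting each observed
record (id, wave j >= 2, among individuals alive at j) by the stabilized
weight

    w*_ij = P(R_ij = 1 | Al_ij = 1, Xbar_ij)
            / P(R_ij = 1 | Al_ij = 1, Xbar_ij, FIbar_ik),   1 <= k < j,

the ratio of an MCAR-model probability (numerator: sex and a study-entry
indicator) to an MAR-model probability (denominator: additionally the FI at
the most recent observed visit — imputed with the sample's mean baseline FI
when none is available — an observed-at-previous-visit indicator, and the
lagged-FI x sex interaction). Both are logistic regressions fit on the
pooled alive person-waves from the second visit onward. Entry-wave records
get weight 1: everyone is observed at entry by construction.

A sensitivity variant adds education and its lagged-FI interaction to the
MAR model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConvergenceError, DataError, SeparationError

__all__ = [
    "build_observation_dataset",
    "fit_observation_models",
    "compute_stabilized_weights",
    "InverseProbabilityWeighter",
    "MAR_TERMS",
    "MCAR_TERMS",
]

MCAR_TERMS = ("sex", "entry_prev")
MAR_TERMS = MCAR_TERMS + ("lag_fi", "prev_observed", "lag_fi_sex")
MAR_TERMS_EDU = MAR_TERMS + ("educ_years", "lag_fi_educ")


def _entry_waves(panel: pd.DataFrame) -> pd.Series:
    """First observed wave per individual (the study-entry wave)."""
    obs = panel.loc[panel["observed"].astype(bool)]
    if obs.empty:
        raise DataError("panel has no observed rows")
    return obs.groupby("id")["wave"].min()


def baseline_mean_fi(panel: pd.DataFrame) -> float:
    """Mean FI at each individual's own first observed wave."""
    obs = panel.loc[panel["observed"].astype(bool) & panel["fi"].notna()]
    if obs.empty:
        raise DataError("no wave with observed FI in the panel")
    first = obs.sort_values("wave", kind="stable").groupby("id").first()
    return float(first["fi"].mean())


def build_observation_dataset(
    panel: pd.DataFrame,
    include_education: bool = False,
    lag_rule: str = "last_observed",
    impute_mean: float | None = None,
) -> pd.DataFrame:
    """Pool the alive person-waves (waves >= 2) for the observation models.

    One row per alive individual-wave after each individual's entry wave,
    with outcome ``r`` (interviewed or not) and the observation-model
    covariates. The lagged FI is the most recent observed FI before the wave
    (``lag_rule="last_observed"``, the default) or strictly the previous
    wave's FI (``lag_rule="previous_wave"``); when unavailable it is imputed
    with the sample mean of baseline FI (``impute_mean`` overrides the
    mean, so bootstrap replicates can reuse their own sample's constant) and
    flagged in ``imputed_lag``.
    """
    if lag_rule not in ("last_observed", "previous_wave"):
        raise DataError(f"unknown lag_rule {lag_rule!r}")
    panel = panel.sort_values(["id", "wave"], kind="stable")
    if impute_mean is None:
        impute_mean = baseline_mean_fi(panel)
    entry = _entry_waves(panel)

    g = panel.groupby("id", sort=False)
    prev_observed = g["observed"].shift(1, fill_value=False)
    prev_wave_fi = g["fi"].shift(1)
    # most recent observed FI strictly before the current wave: shift within
    # the individual, then forward-fill within the individual
    lag_last = prev_wave_fi.groupby(panel["id"]).ffill()

    rows = panel.copy()
    rows["prev_observed"] = prev_observed.astype(float)
    lag = lag_last if lag_rule == "last_observed" else prev_wave_fi
    rows["lag_fi"] = lag
    rows["imputed_lag"] = rows["lag_fi"].isna()
    rows["lag_fi"] = rows["lag_fi"].fillna(impute_mean)
    rows["entry_wave"] = rows["id"].map(entry)
    # indicator that the previous wave was the individual's entry wave
    rows["entry_prev"] = (rows["wave"] == rows["entry_wave"] + 1).astype(float)
    keep = (
        rows["alive"].astype(bool)
        & (rows["wave"] >= 2)
        & (rows["wave"] > rows["entry_wave"])
    )
    rows = rows.loc[keep].copy()
    rows["r"] = rows["observed"].astype(float)
    rows["lag_fi_sex"] = rows["lag_fi"] * rows["sex"]
    out_cols = [
        "id", "wave", "r", "sex", "entry_prev", "lag_fi",
        "prev_observed", "lag_fi_sex", "imputed_lag",
    ]
    if include_education:
        if rows["educ_years"].isna().any():
            raise DataError("education missing on alive rows in sensitivity mode")
        rows["lag_fi_educ"] = rows["lag_fi"] * rows["educ_years"]
        out_cols += ["educ_years", "lag_fi_educ"]
    out = rows[out_cols].reset_index(drop=True)
    out.attrs["impute_mean"] = impute_mean
    out.attrs["n_imputed"] = int(out["imputed_lag"].sum())
    return out


def _fit_logit(endog, exog, penalized: bool):
    if endog.nunique() < 2:
        raise SeparationError(
            "observation outcome is constant; a logistic model cannot be fit "
            "(set penalized=True for a ridge fallback on borderline data)"
        )
    model = sm.Logit(endog, exog)
    try:
        if penalized:
            res = model.fit_regularized(
                method="l1", alpha=1e-4, disp=False, maxiter=200
            )
        else:
            with np.errstate(all="ignore"):
                res = model.fit(disp=False, maxiter=100)
    except Exception as exc:  # statsmodels raises for perfect separation
        raise SeparationError(
            f"logistic fit failed ({exc}); consider penalized=True"
        ) from exc
    converged = bool(getattr(res, "mle_retvals", {}).get("converged", True))
    if not converged and not penalized:
        raise ConvergenceError(
            f"logistic regression did not converge: {res.mle_retvals}"
        )
    return res


def fit_observation_models(
    obs_rows: pd.DataFrame,
    include_education: bool = False,
    penalized: bool = False,
):
    """Fit the MAR (denominator) and MCAR (numerator) logistic models.

    Returns ``(mar_result, mcar_result)`` — statsmodels results carrying
    coefficient vectors and fitted probabilities (``.predict``).
    """
    mar_terms = list(MAR_TERMS_EDU if include_education else MAR_TERMS)
    mcar_terms = list(MCAR_TERMS)
    endog = obs_rows["r"]
    X_mar = sm.add_constant(obs_rows[mar_terms].astype(float), has_constant="add")
    X_mcar = sm.add_constant(obs_rows[mcar_terms].astype(float), has_constant="add")
    mar = _fit_logit(endog, X_mar, penalized)
    mcar = _fit_logit(endog, X_mcar, penalized)
    return mar, mcar


def compute_stabilized_weights(
    panel: pd.DataFrame,
    mar_result,
    mcar_result,
    obs_rows: pd.DataFrame,
    clip: tuple[float, float] | None = (0.01, 0.99),
) -> pd.DataFrame:
    """Stabilized weight table for every observed person-wave.

    Entry-wave records get weight 1. Later observed records get
    ``w* = p_MCAR / p_MAR`` with both probabilities evaluated from the fitted
    models, clipped into ``clip`` before the division (pass ``clip=None`` to
    disable). Columns: id, wave, p_mcar, p_mar, weight, clipped, imputed_lag.
    """
    mar_terms = [c for c in mar_result.model.exog_names if c != "const"]
    mcar_terms = [c for c in mcar_result.model.exog_names if c != "const"]
    p_mar = np.asarray(
        mar_result.predict(
            sm.add_constant(obs_rows[mar_terms].astype(float), has_constant="add")
        )
    )
    p_mcar = np.asarray(
        mcar_result.predict(
            sm.add_constant(obs_rows[mcar_terms].astype(float), has_constant="add")
        )
    )
    clipped = np.zeros(len(obs_rows), dtype=bool)
    if clip is not None:
        lo, hi = clip
        clipped = (p_mar < lo) | (p_mar > hi) | (p_mcar < lo) | (p_mcar > hi)
        p_mar = np.clip(p_mar, lo, hi)
        p_mcar = np.clip(p_mcar, lo, hi)
    if np.any(p_mar <= 0):
        bad = obs_rows.loc[p_mar <= 0, ["id", "wave"]].head()
        raise DataError(f"zero MAR probability; offending rows:\n{bad}")
    tab = obs_rows[["id", "wave", "imputed_lag"]].copy()
    tab["p_mcar"] = p_mcar
    tab["p_mar"] = p_mar
    tab["weight"] = p_mcar / p_mar
    tab["clipped"] = clipped
    # keep only the observed rows — unobserved rows get no weight
    observed_key = panel.loc[
        panel["observed"].astype(bool), ["id", "wave"]
    ]
    tab = observed_key.merge(tab, on=["id", "wave"], how="left")
    entry = _entry_waves(panel)
    is_entry = tab["wave"] == tab["id"].map(entry)
    tab.loc[is_entry, ["p_mcar", "p_mar", "weight"]] = 1.0
    tab.loc[is_entry, ["clipped", "imputed_lag"]] = False
    if tab["weight"].isna().any():
        bad = tab.loc[tab["weight"].isna(), ["id", "wave"]].head()
        raise DataError(f"observed rows without a weight:\n{bad}")
    tab["clipped"] = tab["clipped"].astype(bool)
    tab["imputed_lag"] = tab["imputed_lag"].astype(bool)
    tab.attrs["n_clipped"] = int(tab["clipped"].sum())
    return tab


class InverseProbabilityWeighter(TransformerMixin, BaseEstimator):
    """Sklearn-style estimator producing stabilized observation weights.

    ``fit(panel)`` pools the alive person-waves, fits the MAR and MCAR
    logistic observation models and stores them; ``transform(panel)`` returns
    the weight table for the panel's observed rows. ``fit_transform`` is the
    common path.

    Parameters
    ----------
    include_education : bool, default False
        Sensitivity variant: add education and lagged-FI x education to the
        MAR model.
    clip : (low, high) or None, default (0.01, 0.99)
        Probability clipping applied before the ratio; None disables it.
    lag_rule : {"last_observed", "previous_wave"}
        Which previous FI feeds the MAR model.
    penalized : bool, default False
        Ridge-style fallback for separation-prone samples.

    Attributes
    ----------
    mar_result_, mcar_result_ : fitted statsmodels logistic results
    impute_mean_ : float — the baseline-mean FI used for lag imputation
    n_imputed_ : int
    """

    def __init__(
        self,
        include_education: bool = False,
        clip: tuple[float, float] | None = (0.01, 0.99),
        lag_rule: str = "last_observed",
        penalized: bool = False,
    ):
        self.include_education = include_education
        self.clip = clip
        self.lag_rule = lag_rule
        self.penalized = penalized

    def fit(self, panel: pd.DataFrame, y=None):
        obs_rows = build_observation_dataset(
            panel,
            include_education=self.include_education,
            lag_rule=self.lag_rule,
        )
        self.impute_mean_ = obs_rows.attrs["impute_mean"]
        self.n_imputed_ = obs_rows.attrs["n_imputed"]
        self.obs_rows_ = obs_rows
        self.mar_result_, self.mcar_result_ = fit_observation_models(
            obs_rows,
            include_education=self.include_education,
            penalized=self.penalized,
        )
        return self

    def transform(self, panel: pd.DataFrame) -> pd.DataFrame:
        obs_rows = build_observation_dataset(
            panel,
            include_education=self.include_education,
            lag_rule=self.lag_rule,
            impute_mean=self.impute_mean_,
        )
        return compute_stabilized_weights(
            panel, self.mar_result_, self.mcar_result_, obs_rows, clip=self.clip
        )

    def fit_transform(self, panel: pd.DataFrame, y=None, **fit_params):
        return self.fit(panel).transform(panel)
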