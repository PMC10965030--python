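"""Reference curves: predicted FI quantile trajectories and the pipeline.

A reference curve is the fitted conditional quantile of the FI as a function
of age for a fixed covariate profile (sex, education, age at entry, cohort)
— the longitudinal analogue of pediatric growth centiles. Curves are
reported on the raw age axis; the centering constants recorded in each
:class:`~mortalq.quantile.QuantileFit` make the mapping from profile to
design row unambiguous. 95% bands are percentile intervals of the replicate
predictions from the cluster bootstrap.

Also here: the education-offset utility (how many extra years of education
offset one year of age in the fitted trajectory slope) and
:func:`run_pipeline`, which chains FI construction, weight estimation,
weighted/unweighted quantile fits, bootstrap inference, and curve tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError, SchemaError
from .inference import BootstrapEnsemble, cluster_bootstrap, coefficient_table
from .quantile import FORMULA_TERMS, QuantileFit, fit_all
from .simulate import SimConfig, simulate_cohort, truth_table
from .weights import InverseProbabilityWeighter

__all__ = [
    "CovariateProfile",
    "ReferenceCurve",
    "predict_curve",
    "curve_bands",
    "education_offset_years",
    "run_pipeline",
]


@dataclass
class CovariateProfile:
    """A covariate profile on the raw scale, plus the age grid to predict on."""

    sex: int
    education: float
    baseline_age: float = 65.0
    cohort: int | None = None
    age_grid: np.ndarray = field(
        default_factory=lambda: np.arange(65.0, 91.0, 1.0)
    )

    def __post_init__(self):
        self.age_grid = np.asarray(self.age_grid, float)
        if len(self.age_grid) == 0:
            raise ConfigurationError("age_grid is empty")
        if np.any(np.diff(self.age_grid) <= 0):
            raise ConfigurationError("age_grid must be strictly increasing")
        if self.age_grid[0] < self.baseline_age:
            raise ConfigurationError("age_grid must start at or after baseline_age")


@dataclass
class ReferenceCurve:
    """A predicted quantile trajectory with its percentile band."""

    tau: float
    profile: CovariateProfile
    ages: np.ndarray
    predicted: np.ndarray  # clipped to [0, 1] for display
    predicted_raw: np.ndarray  # pre-clip linear predictions
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    label: str = "weighted"

    def to_frame(self) -> pd.DataFrame:
        d = pd.DataFrame(
            {
                "age": self.ages,
                "fi": self.predicted,
                "fi_unclipped": self.predicted_raw,
            }
        )
        if self.lower is not None:
            d["lower"] = self.lower
            d["upper"] = self.upper
        d.insert(0, "tau", self.tau)
        d.insert(1, "label", self.label)
        return d


def _profile_design(fit: QuantileFit, profile: CovariateProfile) -> np.ndarray:
    """Design rows for the profile along its age grid, using the fit's own
    centering constants."""
    if "cohort" in fit.terms and profile.cohort is None:
        raise SchemaError(
            "profile lacks a cohort value but the fit uses the cohort formula"
        )
    educ_center = fit.centering.get("educ_center", 0.0)
    age_center = fit.centering.get("age_center", 65.0)
    ages = profile.age_grid
    age_c = ages - age_center
    educ_c = profile.education - educ_center
    ba_c = profile.baseline_age - age_center
    boom = float(profile.cohort or 0)
    values = {
        "sex": np.full_like(age_c, float(profile.sex)),
        "educ": np.full_like(age_c, educ_c),
        "base_age": np.full_like(age_c, ba_c),
        "cohort": np.full_like(age_c, boom),
        "age": age_c,
        "age_sex": age_c * profile.sex,
        "age_educ": age_c * educ_c,
        "age_base_age": age_c * ba_c,
        "age_cohort": age_c * boom,
    }
    return np.column_stack(
        [np.ones_like(age_c)] + [values[t] for t in fit.terms]
    )


def predict_curve(fit: QuantileFit, profile: CovariateProfile) -> ReferenceCurve:
    """Predicted FI quantile trajectory for a profile (no band)."""
    D = _profile_design(fit, profile)
    raw = D @ fit.coef.to_numpy()
    return ReferenceCurve(
        tau=fit.tau,
        profile=profile,
        ages=profile.age_grid.copy(),
        predicted=np.clip(raw, 0.0, 1.0),
        predicted_raw=raw,
        label="weighted",
    )


def curve_bands(
    ensemble: BootstrapEnsemble,
    profile: CovariateProfile,
    tau: float,
    level: float = 0.95,
    min_replicates: int = 20,
) -> ReferenceCurve:
    """Reference curve with percentile confidence bands from the bootstrap.

    Per grid age, the band is the ``level`` percentile interval of the
    replicate predictions; bands are built from the unclipped linear
    predictions and the point curve is clipped only for display.
    """
    if tau not in ensemble.replicates:
        raise ConfigurationError(f"tau {tau} not in ensemble")
    if ensemble.n_ok() < min_replicates:
        raise DataError(
            f"need at least {min_replicates} successful replicates for bands, "
            f"have {ensemble.n_ok()}"
        )
    fit = ensemble.point[tau]
    D = _profile_design(fit, profile)
    raw = D @ fit.coef.to_numpy()
    reps = ensemble.replicates[tau].to_numpy()  # (B_ok, p)
    pred_reps = reps @ D.T  # (B_ok, n_ages)
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(pred_reps, alpha, axis=0)
    upper = np.quantile(pred_reps, 1.0 - alpha, axis=0)
    return ReferenceCurve(
        tau=tau,
        profile=profile,
        ages=profile.age_grid.copy(),
        predicted=np.clip(raw, 0.0, 1.0),
        predicted_raw=raw,
        lower=lower,
        upper=upper,
        label="weighted" if ensemble.weighted else "unweighted",
    )


def education_offset_years(fit: QuantileFit | Mapping[str, float]) -> float:
    """Years of education offsetting one year of age in the trajectory slope.

    The fitted age slope for a profile changes by ``beta_age_educ`` per year
    of education, so ``beta_age / |beta_age_educ|`` additional years of
    education compensate the FI increase due to one more year of age. E.g.
    with a median age slope of 0.0067 and an age x education coefficient of
    -0.0004, offsetting one year of ageing takes 16.75 years of education.
    """
    if isinstance(fit, QuantileFit):
        coef = fit.coef
    else:
        coef = pd.Series(dict(fit))
    for term in ("age", "age_educ"):
        if term not in coef.index:
            raise SchemaError(f"fit lacks the {term!r} term")
    beta_a = float(coef["age"])
    beta_ae = float(coef["age_educ"])
    if beta_ae == 0.0:
        raise ConfigurationError(
            "age x education coefficient is zero; the offset is undefined"
        )
    return beta_a / abs(beta_ae)


def _default_profiles(panel: pd.DataFrame, formula: str) -> dict[str, CovariateProfile]:
    mean_educ = float(panel.loc[panel["fi"].notna(), "educ_years"].mean())
    cohort = 0 if formula == "cohort" else None
    return {
        "female": CovariateProfile(sex=1, education=mean_educ, cohort=cohort),
        "male": CovariateProfile(sex=0, education=mean_educ, cohort=cohort),
    }


def run_pipeline(config: Mapping) -> dict:
    """Run the full analysis and return (and optionally write) a bundle.

    Config keys (all optional unless noted):

    - ``panel``: path to a CohortPanel CSV, or ``simulate``: mapping of
      :class:`~mortalq.simulate.SimConfig` overrides (one of the two required)
    - ``formula``: "base" (default) or "cohort"
    - ``taus``: list, default [0.1, 0.5, 0.9]
    - ``bootstrap``: replicate count B (default 200; 0 disables inference)
    - ``seed``: int, default 0
    - ``weighting``: "weighted", "unweighted", or "both" (default "both")
    - ``reestimate_weights``: bool, default True
    - ``sensitivity_education``: bool, default False
    - ``out_dir``: directory to write CSV tables and the run manifest

    Returns a dict with the panel, weight table, fits per mode, coefficient
    tables (Table-2-style layout), curves, and the manifest.
    """
    if ("panel" in config) == ("simulate" in config):
        raise ConfigurationError(
            "config must name exactly one of 'panel' (CSV path) or 'simulate'"
        )
    formula = config.get("formula", "base")
    if formula not in FORMULA_TERMS:
        raise ConfigurationError(f"unknown formula {formula!r}")
    taus = tuple(config.get("taus", (0.1, 0.5, 0.9)))
    B = int(config.get("bootstrap", 200))
    seed = int(config.get("seed", 0))
    weighting = config.get("weighting", "both")
    if weighting not in ("weighted", "unweighted", "both"):
        raise ConfigurationError(f"unknown weighting mode {weighting!r}")

    bundle: dict = {"config": dict(config)}
    if "panel" in config:
        panel = pd.read_csv(config["panel"])
        for col in ("observed", "alive"):
            panel[col] = panel[col].astype(bool)
    else:
        sim = SimConfig(**{**config["simulate"], "seed": seed})
        panel = simulate_cohort(sim)
        bundle["truth"] = truth_table(sim, taus)
        bundle["sim_config"] = sim
    bundle["panel"] = panel

    modes = ["weighted", "unweighted"] if weighting == "both" else [weighting]
    weighter_kwargs = {
        "include_education": bool(config.get("sensitivity_education", False))
    }

    if "weighted" in modes:
        ipw = InverseProbabilityWeighter(**weighter_kwargs)
        bundle["weight_table"] = ipw.fit_transform(panel)
        bundle["weighter"] = ipw

    bundle["fits"] = {}
    bundle["ensembles"] = {}
    bundle["coefficients"] = {}
    bundle["curves"] = {}
    profiles = _default_profiles(panel, formula)
    for mode in modes:
        weighted = mode == "weighted"
        if B > 0:
            ens = cluster_bootstrap(
                panel,
                formula=formula,
                taus=taus,
                B=B,
                seed=seed,
                weighted=weighted,
                reestimate_weights=bool(config.get("reestimate_weights", True)),
                weighter_kwargs=weighter_kwargs,
            )
            bundle["ensembles"][mode] = ens
            bundle["fits"][mode] = ens.point
            coefs = coefficient_table(ens)
            curves = [
                curve_bands(ens, prof, tau)
                for tau in taus
                for prof in profiles.values()
            ]
        else:
            w = bundle.get("weight_table") if weighted else None
            fits = fit_all(panel, weights=w, formula=formula, taus=taus)
            bundle["fits"][mode] = fits
            coefs = pd.DataFrame(
                [
                    {"term": t, "tau": tau, "estimate": fit.coef[t]}
                    for tau, fit in fits.items()
                    for t in fit.coef.index
                ]
            )
            curves = [
                predict_curve(fits[tau], prof)
                for tau in taus
                for prof in profiles.values()
            ]
        for curve, (name, _) in zip(
            curves, [(n, p) for _ in taus for n, p in profiles.items()]
        ):
            curve.label = f"{mode}:{name}"
        bundle["coefficients"][mode] = coefs
        bundle["curves"][mode] = pd.concat(
            [c.to_frame() for c in curves], ignore_index=True
        )

    out_dir = config.get("out_dir")
    if out_dir:
        bundle["manifest"] = _write_bundle(bundle, Path(out_dir), modes)
    return bundle


def _write_bundle(bundle: dict, out_dir: Path, modes: list[str]) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def write_csv(df: pd.DataFrame, name: str):
        path = out_dir / name
        df.to_csv(path, index=False)
        written[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    write_csv(bundle["panel"], "panel.csv")
    if "weight_table" in bundle:
        write_csv(bundle["weight_table"], "weights.csv")
    if "truth" in bundle:
        write_csv(bundle["truth"].reset_index(), "truth.csv")
    for mode in modes:
        write_csv(bundle["coefficients"][mode], f"coefficients_{mode}.csv")
        write_csv(bundle["curves"][mode], f"curves_{mode}.csv")
        if mode in bundle.get("ensembles", {}):
            write_csv(bundle["ensembles"][mode].to_frame(), f"replicates_{mode}.csv")

    import mortalq

    cfg = dict(bundle["config"])
    if "sim_config" in bundle:
        cfg["simulate_resolved"] = bundle["sim_config"].to_dict()
    manifest = {
        "mortalq_version": mortalq.__version__,
        "config": cfg,
        "outputs": written,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
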