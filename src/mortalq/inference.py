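"""Cluster bootstrap and coefficient tests for the quantile-trajectory fits.

Pooled quantile regression under an independence working assumption leaves
the within-person correlation unaccounted for in the point-estimation step,
so standard errors come from a bootstrap for longitudinal data: individuals
(not observations) are resampled with replacement, each carrying all their
waves, preserving the correlation structure. The default is B = 200
replicates. Within a replicate the same resample is used for every quantile
level, so differences of coefficients across quantiles inherit the right
covariance, which is what makes the cross-quantile equality tests valid.

Weight estimation is part of the estimator: by default the observation
models and stabilized weights are re-fit inside every replicate so their
sampling variability enters the standard errors; a fixed-weights mode
reuses the full-sample weights for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConfigurationError,
    DataError,
    DegenerateDistributionError,
    MortalQError,
)
from .quantile import QuantileFit, fit_all
from .weights import InverseProbabilityWeighter

__all__ = [
    "BootstrapEnsemble",
    "TestResult",
    "cluster_bootstrap",
    "resample_individuals",
    "wald_test_zero",
    "cross_quantile_test",
    "coefficient_table",
]


@dataclass
class BootstrapEnsemble:
    """Replicate coefficient vectors per quantile level.

    ``replicates[tau]`` is a (B_ok, p) DataFrame of coefficient vectors
    (columns: intercept + formula terms) from the successful replicates;
    every tau shares the same resample draws replicate-for-replicate.
    ``point`` holds the full-sample fits the tests are centered on.
    """

    formula: str
    taus: tuple[float, ...]
    B: int
    seed: int
    replicates: dict[float, pd.DataFrame]
    point: dict[float, QuantileFit]
    n_failed: int = 0
    weighted: bool = True

    def n_ok(self) -> int:
        return len(next(iter(self.replicates.values())))

    def series(self, term: str, tau: float) -> np.ndarray:
        if tau not in self.replicates:
            raise ConfigurationError(f"tau {tau} not in ensemble {self.taus}")
        df = self.replicates[tau]
        if term not in df.columns:
            raise ConfigurationError(f"term {term!r} not in formula {self.formula!r}")
        return df[term].to_numpy(float)

    def to_frame(self) -> pd.DataFrame:
        """Long replicate-by-coefficient table (for persistence as CSV)."""
        frames = []
        for tau, df in self.replicates.items():
            d = df.copy()
            d.insert(0, "replicate", np.arange(len(d)))
            d.insert(0, "tau", tau)
            frames.append(d)
        return pd.concat(frames, ignore_index=True)


@dataclass
class TestResult:
    """A single Wald-type hypothesis test based on bootstrap SEs."""

    hypothesis: str
    estimate: float
    se: float
    z: float
    p_value: float


def resample_individuals(
    panel: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw n individuals with replacement, keeping all waves together.

    Duplicated individuals receive distinct replicate-local ids so that
    clustering (and any per-id bookkeeping downstream) stays well defined.
    """
    panel = panel.sort_values(["id", "wave"], kind="stable").reset_index(drop=True)
    ids, starts = np.unique(panel["id"].to_numpy(), return_index=True)
    bounds = np.append(starts, len(panel))
    draw = rng.choice(len(ids), size=len(ids), replace=True)
    counts = bounds[draw + 1] - bounds[draw]
    pos = np.concatenate(
        [np.arange(bounds[k], bounds[k + 1]) for k in draw]
    )
    out = panel.iloc[pos].reset_index(drop=True)
    out["id"] = np.repeat(np.arange(len(ids)), counts)
    return out


def cluster_bootstrap(
    panel: pd.DataFrame,
    formula: str = "base",
    taus: Sequence[float] = (0.1, 0.5, 0.9),
    B: int = 200,
    seed: int = 0,
    weighted: bool = True,
    reestimate_weights: bool = True,
    weighter_kwargs: dict | None = None,
    solver: str = "lp",
    max_failure_rate: float = 0.2,
) -> BootstrapEnsemble:
    """Bootstrap the (weighted) quantile fits by resampling individuals.

    Each replicate draws n individuals with replacement with all their
    waves, re-derives the education centering from its own sample, re-fits
    the observation models and stabilized weights when
    ``weighted and reestimate_weights`` (the default — weight estimation is
    part of the estimator), and refits the quantile regression at every tau
    on that one resample. Replicates where any solver fails are dropped and
    counted, not redrawn, keeping the draw sequence seed-stable.
    """
    if B < 1:
        raise ConfigurationError("B must be >= 1")
    rng = np.random.default_rng(seed)
    weighter_kwargs = dict(weighter_kwargs or {})

    # Fixed-weights mode: estimate once on the full sample and let the
    # weights travel with the rows through resampling as a panel column.
    panel = panel.copy()
    if weighted and not reestimate_weights:
        full_w = InverseProbabilityWeighter(**weighter_kwargs).fit_transform(panel)
        panel = panel.merge(
            full_w[["id", "wave", "weight"]].rename(columns={"weight": "_w"}),
            on=["id", "wave"],
            how="left",
        )

    def fit_on(p: pd.DataFrame) -> dict[float, QuantileFit]:
        w = None
        if weighted:
            if reestimate_weights:
                w = InverseProbabilityWeighter(**weighter_kwargs).fit_transform(p)
            else:
                w = p.loc[p["fi"].notna()].set_index(["id", "wave"])["_w"]
        return fit_all(p, weights=w, formula=formula, taus=taus, solver=solver)

    point = fit_on(panel)
    terms = ["intercept"] + list(point[taus[0]].terms)

    rows: dict[float, list[np.ndarray]] = {tau: [] for tau in taus}
    n_failed = 0
    for b in range(B):
        boot = resample_individuals(panel, rng)
        try:
            fits = fit_on(boot)
        except MortalQError:
            n_failed += 1
            continue
        for tau in taus:
            rows[tau].append(fits[tau].coef.to_numpy())
    if n_failed > max_failure_rate * B:
        raise DataError(
            f"{n_failed}/{B} bootstrap replicates failed; use a larger sample "
            "or penalized logistic observation models"
        )
    replicates = {
        tau: pd.DataFrame(np.vstack(rows[tau]), columns=terms) for tau in taus
    }
    return BootstrapEnsemble(
        formula=formula,
        taus=tuple(taus),
        B=B,
        seed=seed,
        replicates=replicates,
        point=point,
        n_failed=n_failed,
        weighted=weighted,
    )


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_test_zero(
    fit: QuantileFit, ensemble: BootstrapEnsemble, term: str
) -> TestResult:
    """Test H0: beta_term(tau) = 0 with the bootstrap SE of the term."""
    series = ensemble.series(term, fit.tau)
    if len(series) < 2:
        raise DataError("need at least 2 successful replicates")
    se = float(np.std(series, ddof=1))
    if se == 0.0:
        raise DegenerateDistributionError(
            f"bootstrap distribution of {term!r} at tau={fit.tau} is degenerate"
        )
    est = fit[term]
    z = est / se
    return TestResult(
        hypothesis=f"beta[{term}](tau={fit.tau:g}) = 0",
        estimate=est,
        se=se,
        z=z,
        p_value=_normal_p(z),
    )


def cross_quantile_test(
    ensemble: BootstrapEnsemble, term: str, tau1: float, tau2: float
) -> TestResult:
    """Test H0: beta_term(tau1) = beta_term(tau2).

    The SE is the standard deviation of the per-replicate differences, which
    captures the covariance induced by sharing resample draws across the two
    quantile levels.
    """
    if tau1 == tau2:
        raise ConfigurationError("tau1 and tau2 must differ")
    s1 = ensemble.series(term, tau1)
    s2 = ensemble.series(term, tau2)
    diff = s1 - s2
    if len(diff) < 2:
        raise DataError("need at least 2 successful replicates")
    se = float(np.std(diff, ddof=1))
    if se == 0.0:
        raise DegenerateDistributionError(
            f"replicate differences of {term!r} between tau={tau1} and "
            f"tau={tau2} are constant"
        )
    est = ensemble.point[tau1][term] - ensemble.point[tau2][term]
    z = est / se
    return TestResult(
        hypothesis=f"beta[{term}](tau={tau1:g}) = beta[{term}](tau={tau2:g})",
        estimate=est,
        se=se,
        z=z,
        p_value=_normal_p(z),
    )


def coefficient_table(ensemble: BootstrapEnsemble) -> pd.DataFrame:
    """Tidy per-term results table across quantile levels.

    One row per (term, tau): estimate, bootstrap SE, p-value for
    H0: beta = 0, and cross-quantile p-values against the adjacent quantile
    levels in the ensemble (columns ``p_vs_tau_<t>``) — the layout used for
    reporting quantile-regression coefficient tables.
    """
    taus = sorted(ensemble.taus)
    records = []
    for tau in taus:
        fit = ensemble.point[tau]
        for term in fit.coef.index:
            wt = wald_test_zero(fit, ensemble, term)
            rec = {
                "term": term,
                "tau": tau,
                "estimate": wt.estimate,
                "se": wt.se,
                "p_value": wt.p_value,
            }
            for other in taus:
                if other != tau:
                    ct = cross_quantile_test(ensemble, term, tau, other)
                    rec[f"p_vs_tau_{other:g}"] = ct.p_value
            records.append(rec)
    return pd.DataFrame.from_records(records)
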