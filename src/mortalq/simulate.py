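"""Synthetic mortal-cohort generator.

Generates long-format panels with the statistical structure the downstream
analysis assumes: a location-scale model for the frailty index (FI) in which
conditional quantiles are linear in age and covariates, an FI-dependent death
process, and missing-at-random intermittent observation. Because the data are
generated from a known location-scale law, the true conditional-quantile
coefficients are available in closed form, which is what makes parameter
recovery testable.

The generative model for individual i at wave j is

    FI_ij = x_ij' beta + (sigma0 + gamma * A_ij) * eps_ij

with A_ij the age centered at 65, eps iid with zero median, and x_ij the
covariate row (sex, education, baseline age, cohort, age, and age
interactions). Under this law the tau-th conditional quantile is linear with
intercept beta_0 + sigma0 * q_eps(tau) and age slope beta_a + gamma *
q_eps(tau); all other coefficients are unchanged. A positive gamma therefore
makes the age slope strictly increasing in tau — upper frailty quantiles
progress faster, the pattern the weighted analysis is designed to recover in
the presence of death.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .exceptions import ConfigurationError

__all__ = [
    "SimConfig",
    "DEFAULT_COEF_LOCATION",
    "simulate_cohort",
    "true_quantile_coefficients",
    "truth_table",
    "apply_death_process",
    "apply_observation_process",
    "simulate_deficit_items",
    "COEF_NAMES",
]

#: Coefficient names of the data-generating location model, in design order.
COEF_NAMES = (
    "intercept",
    "sex",
    "educ",
    "base_age",
    "cohort",
    "age",
    "age_sex",
    "age_educ",
    "age_base_age",
    "age_cohort",
)

#: Default location coefficients. Magnitudes follow the weighted median
#: estimates reported for European survey cohorts of this design (FI scale
#: 0-1, age in years past 65, education in years from the mean).
DEFAULT_COEF_LOCATION: dict[str, float] = {
    "intercept": 0.15,
    "sex": 0.004,
    "educ": -0.0008,
    "base_age": -0.005,
    "cohort": 0.008,
    "age": 0.0067,
    "age_sex": 0.0020,
    "age_educ": -0.0004,
    "age_base_age": 0.0004,
    "age_cohort": 0.0007,
}


@dataclass
class SimConfig:
    """Configuration of the synthetic mortal-cohort generator.

    Defaults emulate a biennial European ageing panel: entry at 65+, six
    waves two years apart, right-skew-compatible FI levels around 0.15,
    roughly 21-22% deaths over follow-up driven by the FI, and heavy
    intermittent missingness with frailer individuals less likely to be
    re-interviewed.

    Parameters
    ----------
    n_individuals : int
        Number of individuals enrolled at wave 1.
    n_waves : int
        Number of biennial waves (>= 2).
    wave_gap_years : float
        Years between consecutive waves.
    entry_age_range : (float, float)
        Uniform range of age at study entry; minimum must be >= 65.
    coef_location : mapping
        Location coefficients, keys from :data:`COEF_NAMES`.
    scale_intercept : float
        sigma0 > 0, residual scale at age 65.
    scale_age : float
        gamma, the per-year change of the residual scale with age
        (heteroscedasticity; makes quantile slopes differ by tau).
    error_dist : {"normal", "skew-positive"}
        Residual law. "normal" is N(0,1); "skew-positive" is a unit
        exponential shifted to have median zero (right skew, like the FI).
    error_corr : float in [0, 1)
        Exchangeable within-person correlation of the residuals, built from
        a shared per-person component without changing the marginal law
        (normal: sqrt(rho) b_i + sqrt(1-rho) e_ij; skew-positive:
        Gamma(rho) + Gamma(1-rho) = Exp(1) by additivity). Frailty is
        strongly persistent within a person, and this persistence is what
        makes frailty-dependent missingness informative — with rho = 0 the
        lagged-FI observation process would not bias the quantile fits at
        all and the weighting correction would have nothing to correct.
    death_model : (float, float, float)
        (intercept, coef_on_FI, coef_on_age) of the per-wave logistic death
        hazard evaluated on the current true FI and age - 65.
    obs_model : (float, float, float)
        (intercept, coef_on_lagFI, coef_on_sex) of the per-wave logistic
        probability of being interviewed given alive; the lag is the true FI
        at the previous wave.
    prop_female : float
        Share of women.
    educ_mean, educ_sd : float
        Years of full-time education (normal, truncated at 0).
    prop_born_1946plus : float
        Share born in 1946 or later.
    seed : int
        Seed for all randomness.
    """

    n_individuals: int = 2000
    n_waves: int = 6
    wave_gap_years: float = 2.0
    entry_age_range: tuple[float, float] = (65.0, 85.0)
    coef_location: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEF_LOCATION)
    )
    scale_intercept: float = 0.05
    scale_age: float = 0.003
    error_dist: str = "normal"
    error_corr: float = 0.6
    death_model: tuple[float, float, float] = (-5.25, 4.0, 0.05)
    obs_model: tuple[float, float, float] = (0.75, -2.0, 0.1)
    prop_female: float = 0.53
    educ_mean: float = 9.6
    educ_sd: float = 4.5
    prop_born_1946plus: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        if self.n_waves < 2:
            raise ConfigurationError("n_waves must be >= 2")
        if self.wave_gap_years <= 0:
            raise ConfigurationError("wave_gap_years must be > 0")
        lo, hi = self.entry_age_range
        if lo < 65.0 or hi < lo:
            raise ConfigurationError(
                "entry_age_range must satisfy 65 <= low <= high"
            )
        unknown = set(self.coef_location) - set(COEF_NAMES)
        if unknown:
            raise ConfigurationError(
                f"coef_location has unknown keys: {sorted(unknown)}"
            )
        if self.scale_intercept <= 0:
            raise ConfigurationError("scale_intercept must be > 0")
        max_age_c = hi - 65.0 + self.wave_gap_years * (self.n_waves - 1)
        if self.scale_intercept + self.scale_age * max_age_c <= 0:
            raise ConfigurationError(
                "scale_age: residual scale is non-positive at the oldest "
                "simulated age"
            )
        if self.error_dist not in ("normal", "skew-positive"):
            raise ConfigurationError(
                f"error_dist must be 'normal' or 'skew-positive', "
                f"got {self.error_dist!r}"
            )
        if not 0.0 <= self.error_corr < 1.0:
            raise ConfigurationError("error_corr must be in [0, 1)")
        for name, val in (
            ("prop_female", self.prop_female),
            ("prop_born_1946plus", self.prop_born_1946plus),
        ):
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.educ_sd < 0:
            raise ConfigurationError("educ_sd must be >= 0")

    def coef_vector(self) -> np.ndarray:
        """Location coefficients in :data:`COEF_NAMES` order (absent -> 0)."""
        return np.array([self.coef_location.get(k, 0.0) for k in COEF_NAMES])

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["coef_location"] = dict(self.coef_location)
        return d


def _error_quantile(error_dist: str, tau: float) -> float:
    """Quantile function of the standardized (zero-median) residual law."""
    if error_dist == "normal":
        return float(stats.norm.ppf(tau))
    if error_dist == "skew-positive":
        # Exp(1) shifted by its median log 2: q(tau) = -log(1-tau) - log 2.
        return float(-math.log1p(-tau) - math.log(2.0))
    raise ConfigurationError(
        f"error_dist {error_dist!r} has no quantile function"
    )


def _draw_errors(
    error_dist: str, n: int, J: int, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """(n, J) residuals, exchangeable within rows with correlation rho.

    The marginal law is exactly the declared one: for normal residuals a
    shared N(0,1) person component enters with weight sqrt(rho); for the
    skew-positive law, Gamma(rho, 1) + Gamma(1 - rho, 1) = Exp(1) by gamma
    additivity, shifted by its median log 2.
    """
    if error_dist == "normal":
        person = rng.standard_normal((n, 1))
        occasion = rng.standard_normal((n, J))
        return math.sqrt(rho) * person + math.sqrt(1.0 - rho) * occasion
    if error_dist == "skew-positive":
        person = rng.gamma(rho, 1.0, (n, 1)) if rho > 0 else np.zeros((n, 1))
        occasion = rng.gamma(1.0 - rho, 1.0, (n, J))
        return person + occasion - math.log(2.0)
    raise ConfigurationError(f"unsupported error_dist {error_dist!r}")


def true_quantile_coefficients(config: SimConfig, tau: float) -> dict[str, float]:
    """Closed-form true conditional-quantile coefficients at ``tau``.

    Under the location-scale law only the intercept and the age coefficient
    depend on tau: the intercept shifts by ``sigma0 * q_eps(tau)`` and the age
    slope by ``gamma * q_eps(tau)``; every other coefficient is shared across
    quantiles because the residual scale depends on age alone.
    """
    config.validate()
    if not 0.0 < tau < 1.0:
        raise ConfigurationError("tau must be in (0, 1)")
    q = _error_quantile(config.error_dist, tau)
    truth = {k: config.coef_location.get(k, 0.0) for k in COEF_NAMES}
    truth["intercept"] += config.scale_intercept * q
    truth["age"] += config.scale_age * q
    return truth


def truth_table(config: SimConfig, taus=(0.1, 0.5, 0.9)) -> pd.DataFrame:
    """True coefficient table, one row per coefficient, one column per tau."""
    cols = {f"tau_{tau:g}": true_quantile_coefficients(config, tau) for tau in taus}
    return pd.DataFrame(cols).rename_axis("term")


def _design_block(panel: pd.DataFrame, educ_center: float) -> np.ndarray:
    """Generative design matrix (COEF_NAMES order) on centered covariates."""
    age_c = panel["age"].to_numpy() - 65.0
    sex = panel["sex"].to_numpy(float)
    educ_c = panel["educ_years"].to_numpy() - educ_center
    ba_c = panel["base_age"].to_numpy() - 65.0
    boom = panel["born_1946plus"].to_numpy(float)
    return np.column_stack(
        [
            np.ones(len(panel)),
            sex,
            educ_c,
            ba_c,
            boom,
            age_c,
            age_c * sex,
            age_c * educ_c,
            age_c * ba_c,
            age_c * boom,
        ]
    )


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Simulate a full mortal-cohort panel.

    Returns a long DataFrame with one row per individual x wave and columns
    ``id, wave, age, sex, educ_years, base_age, born_1946plus, fi, observed,
    alive, fi_true``. ``fi`` is the analysis outcome: the latent ``fi_true``
    where observed, NaN otherwise. The number of latent FI values clamped to
    [0, 1] is reported in ``panel.attrs["n_clamped"]`` (and the fraction in
    ``"clamp_fraction"``); default parameters keep it below 1% so the
    closed-form truth remains valid to tolerance.

    Deterministic given ``config`` (including its seed).
    """
    config.validate()
    n, J = config.n_individuals, config.n_waves
    ss = np.random.SeedSequence(config.seed)
    rng_cov, rng_err, seed_death, seed_obs = ss.spawn(4)
    rng_cov = np.random.default_rng(rng_cov)
    rng_err = np.random.default_rng(rng_err)

    lo, hi = config.entry_age_range
    base_age = rng_cov.uniform(lo, hi, n)
    sex = (rng_cov.random(n) < config.prop_female).astype(int)
    educ = np.clip(
        rng_cov.normal(config.educ_mean, config.educ_sd, n), 0.0, None
    )
    boom = (rng_cov.random(n) < config.prop_born_1946plus).astype(int)

    ids = np.repeat(np.arange(n), J)
    waves = np.tile(np.arange(1, J + 1), n)
    age = base_age[ids] + config.wave_gap_years * (waves - 1)

    panel = pd.DataFrame(
        {
            "id": ids,
            "wave": waves,
            "age": age,
            "sex": sex[ids],
            "educ_years": educ[ids],
            "base_age": base_age[ids],
            "born_1946plus": boom[ids],
        }
    )

    X = _design_block(panel, educ_center=config.educ_mean)
    location = X @ config.coef_vector()
    scale = config.scale_intercept + config.scale_age * (age - 65.0)
    eps = _draw_errors(
        config.error_dist, n, J, config.error_corr, rng_err
    ).reshape(-1)
    fi_raw = location + scale * eps
    fi_true = np.clip(fi_raw, 0.0, 1.0)
    n_clamped = int(np.sum((fi_raw < 0.0) | (fi_raw > 1.0)))
    panel["fi_true"] = fi_true

    panel = apply_death_process(panel, config.death_model, seed_death)
    panel = apply_observation_process(panel, config.obs_model, seed_obs)

    panel["fi"] = np.where(panel["observed"].to_numpy(bool), fi_true, np.nan)
    panel = panel[
        [
            "id",
            "wave",
            "age",
            "sex",
            "educ_years",
            "base_age",
            "born_1946plus",
            "fi",
            "observed",
            "alive",
            "fi_true",
        ]
    ]
    panel.attrs["n_clamped"] = n_clamped
    panel.attrs["clamp_fraction"] = n_clamped / len(panel)
    panel.attrs["config"] = config.to_dict()
    return panel


def apply_death_process(panel: pd.DataFrame, death_model, seed) -> pd.DataFrame:
    """Stamp ``alive`` flags via a per-wave logistic hazard; death is absorbing.

    Everyone is alive at wave 1 (they enrolled). At each later wave the
    hazard ``expit(b0 + b_fi * FI_ij + b_age * (age_ij - 65))`` is evaluated
    on the current true FI and age; a death at wave j makes the individual
    dead at wave j and every wave after.
    """
    b0, b_fi, b_age = (float(v) for v in death_model)
    rng = np.random.default_rng(seed)
    panel = panel.sort_values(["id", "wave"], kind="stable").reset_index(drop=True)
    n_waves = panel["wave"].max()
    wide_fi = panel.pivot(index="id", columns="wave", values="fi_true")
    wide_age = panel.pivot(index="id", columns="wave", values="age")
    n = wide_fi.shape[0]
    alive = np.ones((n, n_waves), dtype=bool)
    for j in range(1, n_waves):  # waves 2..J, 0-based column j
        hazard = expit(
            b0
            + b_fi * wide_fi.iloc[:, j].to_numpy()
            + b_age * (wide_age.iloc[:, j].to_numpy() - 65.0)
        )
        dies = rng.random(n) < hazard
        alive[:, j] = alive[:, j - 1] & ~dies
    alive_long = pd.DataFrame(
        alive, index=wide_fi.index, columns=wide_fi.columns
    ).stack()
    key = pd.MultiIndex.from_frame(panel[["id", "wave"]])
    panel["alive"] = alive_long.reindex(key).to_numpy().astype(bool)
    return panel


def apply_observation_process(panel: pd.DataFrame, obs_model, seed) -> pd.DataFrame:
    """Stamp ``observed`` flags: wave 1 always observed, dead rows never.

    For alive rows at waves >= 2 the interview probability is
    ``expit(c0 + c_lag * FI_{i,j-1} + c_sex * sex_i)`` where the lag is the
    previous wave's *true* FI — the generator's own history, which the
    downstream weight models can only approximate from observed records.
    """
    c0, c_lag, c_sex = (float(v) for v in obs_model)
    rng = np.random.default_rng(seed)
    panel = panel.sort_values(["id", "wave"], kind="stable").reset_index(drop=True)
    n_waves = panel["wave"].max()
    wide_fi = panel.pivot(index="id", columns="wave", values="fi_true")
    wide_alive = panel.pivot(index="id", columns="wave", values="alive").astype(bool)
    sex = panel.drop_duplicates("id").set_index("id")["sex"].reindex(wide_fi.index)
    n = wide_fi.shape[0]
    observed = np.zeros((n, n_waves), dtype=bool)
    observed[:, 0] = True
    for j in range(1, n_waves):
        p_obs = expit(
            c0
            + c_lag * wide_fi.iloc[:, j - 1].to_numpy()
            + c_sex * sex.to_numpy(float)
        )
        observed[:, j] = wide_alive.iloc[:, j].to_numpy() & (rng.random(n) < p_obs)
    obs_long = pd.DataFrame(
        observed, index=wide_fi.index, columns=wide_fi.columns
    ).stack()
    key = pd.MultiIndex.from_frame(panel[["id", "wave"]])
    panel["observed"] = obs_long.reindex(key).to_numpy().astype(bool)
    return panel


def simulate_deficit_items(
    fi_values: np.ndarray, n_items: int = 40, missing_rate: float = 0.05, seed=0
) -> pd.DataFrame:
    """Draw a binary deficit-item panel whose item mean matches given FI values.

    Each of ``n_items`` items is Bernoulli(FI) per row, then a fraction
    ``missing_rate`` of entries is masked at random. Used to exercise the
    frailty-index construction against a known underlying FI.
    """
    fi_values = np.asarray(fi_values, float)
    rng = np.random.default_rng(seed)
    items = (rng.random((len(fi_values), n_items)) < fi_values[:, None]).astype(float)
    mask = rng.random(items.shape) < missing_rate
    items[mask] = np.nan
    return pd.DataFrame(items, columns=[f"item_{k + 1:02d}" for k in range(n_items)])
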