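"""Synthetic mortal-cohort generator: contracts, closed-form truth, processes."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from mortalq import SimConfig, simulate_cohort, true_quantile_coefficients, truth_table
from mortalq.exceptions import ConfigurationError
from mortalq.simulate import apply_death_process, apply_observation_process

Z90 = 1.2815515655446004  # standard-normal 0.9 quantile (frozen constant)


def degenerate_config(**kw):
    """No death, everyone observed."""
    base = dict(
        n_individuals=100,
        seed=1,
        death_model=(-50.0, 0.0, 0.0),
        obs_model=(50.0, 0.0, 0.0),
    )
    base.update(kw)
    return SimConfig(**base)


class TestSimulateCohort:
    def test_degenerate_processes_full_panel(self):
        panel = simulate_cohort(degenerate_config())
        assert len(panel) == 600
        assert panel["observed"].all()
        assert panel["alive"].all()
        assert panel["fi"].notna().all()

    def test_determinism_same_seed(self):
        cfg = SimConfig(n_individuals=150, seed=77)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = simulate_cohort(SimConfig(n_individuals=150, seed=1))
        b = simulate_cohort(SimConfig(n_individuals=150, seed=2))
        assert not a["fi_true"].equals(b["fi_true"])

    def test_alive_monotone_and_observed_implies_alive(self, mortal_panel):
        wide = mortal_panel.pivot(index="id", columns="wave", values="alive")
        assert (wide.astype(int).diff(axis=1).fillna(0) <= 0).all().all()
        assert not (mortal_panel["observed"] & ~mortal_panel["alive"]).any()
        wave1 = mortal_panel.query("wave == 1")
        assert wave1["observed"].all()

    def test_fi_bounds_and_clamp_reporting(self, mortal_panel):
        assert mortal_panel["fi_true"].between(0, 1).all()
        assert "n_clamped" in mortal_panel.attrs
        assert mortal_panel.attrs["clamp_fraction"] < 0.01

    def test_fi_missing_iff_unobserved(self, mortal_panel):
        assert (mortal_panel["fi"].notna() == mortal_panel["observed"]).all()

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_waves", 1),
            ("scale_intercept", 0.0),
            ("entry_age_range", (60.0, 80.0)),
            ("error_dist", "cauchy"),
            ("prop_female", 1.5),
            ("error_corr", 1.0),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        with pytest.raises(ConfigurationError):
            SimConfig(**{field: value}).validate()

    def test_error_corr_induces_within_person_correlation(self):
        cfg = degenerate_config(
            n_individuals=2000, seed=9, error_corr=0.6, scale_age=0.0
        )
        panel = simulate_cohort(cfg)
        from mortalq.simulate import _design_block

        X = _design_block(panel, educ_center=cfg.educ_mean)
        eps = (panel["fi_true"].to_numpy() - X @ cfg.coef_vector()) / cfg.scale_intercept
        wide = pd.DataFrame(
            {"id": panel["id"], "wave": panel["wave"], "eps": eps}
        ).pivot(index="id", columns="wave", values="eps")
        corr = wide.corr().to_numpy()
        off_diag = corr[np.triu_indices_from(corr, k=1)]
        assert abs(off_diag.mean() - 0.6) < 0.05


class TestTruth:
    def test_median_truth_equals_location_for_symmetric_error(self):
        cfg = SimConfig()
        truth = true_quantile_coefficients(cfg, 0.5)
        for name, value in cfg.coef_location.items():
            assert truth[name] == pytest.approx(value, abs=1e-15)

    def test_skew_positive_median_truth_equals_location(self):
        cfg = SimConfig(error_dist="skew-positive")
        truth = true_quantile_coefficients(cfg, 0.5)
        assert truth["age"] == pytest.approx(cfg.coef_location["age"], abs=1e-12)
        assert truth["intercept"] == pytest.approx(
            cfg.coef_location["intercept"], abs=1e-12
        )

    def test_upper_quantile_age_slope_location_scale(self):
        cfg = SimConfig(
            coef_location={**SimConfig().coef_location, "age": 0.005},
            scale_age=0.003,
        )
        truth = true_quantile_coefficients(cfg, 0.9)
        assert truth["age"] == pytest.approx(0.005 + 0.003 * Z90, abs=1e-9)
        assert truth["age"] == pytest.approx(0.0088446547, abs=1e-7)

    def test_intercept_shift_only_when_scale_constant(self):
        cfg = SimConfig(scale_intercept=0.05, scale_age=0.0)
        truth = true_quantile_coefficients(cfg, 0.9)
        assert truth["intercept"] == pytest.approx(
            cfg.coef_location["intercept"] + 0.05 * Z90, abs=1e-9
        )
        assert truth["age"] == pytest.approx(cfg.coef_location["age"], abs=1e-15)

    def test_symmetric_error_gives_antisymmetric_shifts(self):
        cfg = SimConfig()
        t_lo = true_quantile_coefficients(cfg, 0.1)
        t_hi = true_quantile_coefficients(cfg, 0.9)
        base = cfg.coef_location
        assert t_hi["intercept"] - base["intercept"] == pytest.approx(
            -(t_lo["intercept"] - base["intercept"]), abs=1e-12
        )
        assert t_hi["age"] - base["age"] == pytest.approx(
            -(t_lo["age"] - base["age"]), abs=1e-12
        )

    def test_age_slope_strictly_increasing_in_tau_for_positive_gamma(self):
        cfg = SimConfig(scale_age=0.003)
        table = truth_table(cfg, taus=(0.1, 0.25, 0.5, 0.75, 0.9))
        slopes = table.loc["age"].to_numpy()
        assert np.all(np.diff(slopes) > 0)

    def test_unsupported_error_dist(self):
        cfg = SimConfig()
        object.__setattr__(cfg, "error_dist", "triangular")
        with pytest.raises(ConfigurationError):
            true_quantile_coefficients(cfg, 0.5)


class TestDeathProcess:
    def test_zero_hazard_everyone_survives(self):
        panel = simulate_cohort(degenerate_config())
        assert panel["alive"].all()

    def test_constant_hazard_death_fraction(self):
        cfg = degenerate_config(
            n_individuals=5000, death_model=(float(logit(0.1)), 0.0, 0.0), seed=3
        )
        panel = simulate_cohort(cfg)
        wide = panel.pivot(index="id", columns="wave", values="alive")
        at_risk = dead = 0
        for j in range(1, 6):
            risk = wide.iloc[:, j - 1]
            at_risk += int(risk.sum())
            dead += int((risk & ~wide.iloc[:, j]).sum())
        rate = dead / at_risk
        se = np.sqrt(0.1 * 0.9 / at_risk)
        assert abs(rate - 0.10) < 4 * se

    def test_fi_dependent_death_selects_frail(self):
        cfg = degenerate_config(n_individuals=3000, death_model=(-3.0, 5.0, 0.0), seed=4)
        panel = simulate_cohort(cfg)
        died = ~panel.groupby("id")["alive"].min().astype(bool)
        baseline = panel.query("wave == 1").set_index("id")["fi_true"]
        assert baseline[died].mean() > baseline[~died].mean()

    def test_death_is_absorbing(self):
        panel = simulate_cohort(SimConfig(n_individuals=400, seed=5))
        wide = panel.pivot(index="id", columns="wave", values="alive").astype(int)
        assert (wide.diff(axis=1).fillna(0) <= 0).all().all()


class TestObservationProcess:
    def test_probability_one_observes_all_alive(self):
        cfg = SimConfig(n_individuals=500, seed=6, obs_model=(50.0, 0.0, 0.0))
        panel = simulate_cohort(cfg)
        assert (panel["observed"] == panel["alive"]).all()

    def test_negative_lag_fi_selection_direction(self):
        cfg = degenerate_config(
            n_individuals=3000, obs_model=(1.0, -3.0, 0.0), seed=7
        )
        panel = simulate_cohort(cfg).sort_values(["id", "wave"])
        lag = panel.groupby("id")["fi_true"].shift(1)
        later = panel["wave"] >= 2
        obs = panel.loc[later & panel["observed"], :].index
        unobs = panel.loc[later & ~panel["observed"], :].index
        assert lag[obs].mean() < lag[unobs].mean()

    def test_constant_probability_observation_rate(self):
        cfg = degenerate_config(
            n_individuals=5000, obs_model=(float(logit(0.7)), 0.0, 0.0), seed=8
        )
        panel = simulate_cohort(cfg)
        later = panel["wave"] >= 2
        rate = panel.loc[later, "observed"].mean()
        n = int(later.sum())
        assert abs(rate - 0.70) < 4 * np.sqrt(0.7 * 0.3 / n)

    def test_study_conditions_at_defaults(self):
        """Defaults emulate the target panel: ~21-22% deaths, heavy
        intermittent missingness with ~22-29% seen only once or twice."""
        panel = simulate_cohort(SimConfig(n_individuals=4000, seed=9))
        died = (~panel.groupby("id")["alive"].min().astype(bool)).mean()
        n_interviews = panel.groupby("id")["observed"].sum()
        assert 0.17 <= died <= 0.27
        assert 0.18 <= (n_interviews <= 2).mean() <= 0.33
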