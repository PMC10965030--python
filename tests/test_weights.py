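"""Stabilized observation weights: pooling rules, logistic fits, the ratio."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from mortalq import InverseProbabilityWeighter, fit_all, simulate_cohort
from mortalq.exceptions import DataError, SeparationError
from mortalq.simulate import SimConfig
from mortalq.weights import (
    build_observation_dataset,
    compute_stabilized_weights,
    fit_observation_models,
)


def tiny_panel(rows):
    """Panel from (id, wave, fi, observed, alive) tuples; covariates constant."""
    df = pd.DataFrame(rows, columns=["id", "wave", "fi", "observed", "alive"])
    df["age"] = 63.0 + 2.0 * df["wave"]
    df["sex"] = df["id"] % 2
    df["educ_years"] = 10.0
    df["base_age"] = 65.0
    df["born_1946plus"] = 0
    return df


class TestObservationDataset:
    def test_fully_observed_individual(self):
        panel = tiny_panel(
            [(1, 1, 0.10, True, True), (1, 2, 0.20, True, True),
             (1, 3, 0.30, True, True)]
        )
        rows = build_observation_dataset(panel)
        assert len(rows) == 2
        assert rows["wave"].tolist() == [2, 3]
        assert rows["lag_fi"].tolist() == [0.10, 0.20]
        assert not rows["imputed_lag"].any()
        assert rows["r"].tolist() == [1.0, 1.0]

    def test_last_observed_lag_carries_forward(self):
        panel = tiny_panel(
            [(1, 1, 0.10, True, True), (1, 2, np.nan, False, True),
             (1, 3, np.nan, False, True)]
        )
        rows = build_observation_dataset(panel)
        assert rows["lag_fi"].tolist() == [0.10, 0.10]
        assert not rows["imputed_lag"].any()
        assert rows["prev_observed"].tolist() == [1.0, 0.0]

    def test_previous_wave_rule_imputes_gaps(self):
        panel = tiny_panel(
            [(1, 1, 0.10, True, True), (1, 2, np.nan, False, True),
             (1, 3, np.nan, False, True),
             (2, 1, 0.30, True, True), (2, 2, 0.40, True, True),
             (2, 3, 0.50, True, True)]
        )
        rows = build_observation_dataset(panel, lag_rule="previous_wave")
        r1 = rows[rows["id"] == 1]
        # wave 3 has no wave-2 FI: imputed with mean baseline FI (0.2)
        assert r1["lag_fi"].tolist() == pytest.approx([0.10, 0.20])
        assert r1["imputed_lag"].tolist() == [False, True]

    def test_dead_waves_excluded(self):
        panel = tiny_panel(
            [(1, 1, 0.10, True, True), (1, 2, 0.20, True, True),
             (1, 3, np.nan, False, False)]
        )
        rows = build_observation_dataset(panel)
        assert rows["wave"].tolist() == [2]

    def test_entry_indicator_marks_first_post_entry_wave(self):
        panel = tiny_panel(
            [(1, 1, 0.10, True, True), (1, 2, 0.15, True, True),
             (1, 3, 0.20, True, True)]
        )
        rows = build_observation_dataset(panel)
        assert rows["entry_prev"].tolist() == [1.0, 0.0]

    def test_sensitivity_mode_adds_education_terms(self):
        panel = tiny_panel(
            [(1, 1, 0.10, True, True), (1, 2, 0.20, True, True)]
        )
        rows = build_observation_dataset(panel, include_education=True)
        assert "educ_years" in rows.columns
        assert rows["lag_fi_educ"].iloc[0] == pytest.approx(1.0)

    def test_no_observed_fi_raises(self):
        panel = tiny_panel([(1, 1, np.nan, False, True)])
        with pytest.raises(DataError):
            build_observation_dataset(panel)


class TestObservationModels:
    def test_constant_outcome_raises_separation(self):
        panel = tiny_panel(
            [(i, w, 0.1 * w, True, True) for i in range(1, 6) for w in (1, 2, 3)]
        )
        rows = build_observation_dataset(panel)
        with pytest.raises(SeparationError):
            fit_observation_models(rows)

    def test_logistic_recovery_of_known_model(self):
        # R ~ logistic(a + b*lag_fi) on a large simulated dataset: ML should
        # recover the generating coefficients within 3 SE.
        rng = np.random.default_rng(0)
        n = 10_000
        rows = pd.DataFrame(
            {
                "sex": rng.integers(0, 2, n).astype(float),
                "entry_prev": rng.integers(0, 2, n).astype(float),
                "lag_fi": rng.uniform(0, 0.6, n),
                "prev_observed": rng.integers(0, 2, n).astype(float),
            }
        )
        rows["lag_fi_sex"] = rows["lag_fi"] * rows["sex"]
        true = {"const": 1.0, "sex": 0.2, "entry_prev": -0.3, "lag_fi": -2.0,
                "prev_observed": 0.5, "lag_fi_sex": 0.4}
        lin = (true["const"] + true["sex"] * rows["sex"]
               + true["entry_prev"] * rows["entry_prev"]
               + true["lag_fi"] * rows["lag_fi"]
               + true["prev_observed"] * rows["prev_observed"]
               + true["lag_fi_sex"] * rows["lag_fi_sex"])
        rows["r"] = (rng.random(n) < expit(lin)).astype(float)
        mar, _ = fit_observation_models(rows)
        for name, value in true.items():
            assert abs(mar.params[name] - value) < 3 * mar.bse[name]

    def test_mcar_intercept_calibration(self, mortal_panel):
        # with an intercept, logistic ML equates mean fitted probability to
        # the observed rate — a sharp calibration identity
        rows = build_observation_dataset(mortal_panel)
        _, mcar = fit_observation_models(rows)
        assert mcar.predict().mean() == pytest.approx(rows["r"].mean(), abs=1e-8)


class TestStabilizedWeights:
    def test_ratio_formula(self, mortal_panel):
        table = InverseProbabilityWeighter(clip=None).fit_transform(mortal_panel)
        # the weight is exactly the ratio of the two fitted probabilities
        np.testing.assert_allclose(
            table["weight"], table["p_mcar"] / table["p_mar"], rtol=1e-12
        )
        later = table[table["wave"] >= 2]
        probe = later.iloc[0]
        assert probe["weight"] == pytest.approx(
            probe["p_mcar"] / probe["p_mar"], rel=1e-12
        )

    def test_entry_wave_weight_is_one(self, mortal_panel):
        table = InverseProbabilityWeighter().fit_transform(mortal_panel)
        w1 = table[table["wave"] == 1]
        assert (w1["weight"] == 1.0).all()

    def test_every_observed_row_weighted_once(self, mortal_panel):
        table = InverseProbabilityWeighter().fit_transform(mortal_panel)
        obs = mortal_panel.loc[mortal_panel["observed"], ["id", "wave"]]
        assert len(table) == len(obs)
        assert (table["weight"] > 0).all()
        merged = obs.merge(table, on=["id", "wave"], how="left")
        assert merged["weight"].notna().all()

    def test_relabeling_invariance(self, mortal_panel):
        table = InverseProbabilityWeighter().fit_transform(mortal_panel)
        relabeled = mortal_panel.copy()
        relabeled["id"] = relabeled["id"] + 10_000
        table2 = InverseProbabilityWeighter().fit_transform(relabeled)
        np.testing.assert_allclose(table["weight"], table2["weight"], rtol=1e-10)

    def test_null_selection_weights_near_one(self):
        # observation ignores frailty: MAR and MCAR coincide in truth
        cfg = SimConfig(
            n_individuals=2000, seed=5, obs_model=(float(logit(0.75)), 0.0, 0.0)
        )
        panel = simulate_cohort(cfg)
        table = InverseProbabilityWeighter().fit_transform(panel)
        w = table["weight"].to_numpy()
        assert abs(w.mean() - 1.0) < 0.01
        assert np.abs(w - 1.0).mean() < 0.03

    def test_informative_selection_upweights_frail(self, mortal_panel):
        table = InverseProbabilityWeighter().fit_transform(mortal_panel)
        merged = mortal_panel.merge(table, on=["id", "wave"])
        later = merged[merged["wave"] >= 2]
        frail = later["fi"] > later["fi"].median()
        assert later.loc[frail, "weight"].mean() > later.loc[~frail, "weight"].mean()

    def test_weighted_mean_corrects_mar_selection(self):
        # IPW oracle check: the weighted mean of the observed FI should sit
        # closer to the full alive-population mean than the unweighted mean
        cfg = SimConfig(
            n_individuals=5000, seed=11,
            death_model=(-50.0, 0.0, 0.0), obs_model=(1.0, -3.0, 0.0),
        )
        panel = simulate_cohort(cfg)
        table = InverseProbabilityWeighter().fit_transform(panel)
        merged = panel.merge(table, on=["id", "wave"])
        later = merged[merged["wave"] >= 2]
        full_mean = panel.loc[panel["wave"] >= 2, "fi_true"].mean()
        unweighted = later["fi"].mean()
        weighted = np.average(later["fi"], weights=later["weight"])
        assert abs(weighted - full_mean) < abs(unweighted - full_mean)

    def test_clipping_reported(self, mortal_panel):
        table = InverseProbabilityWeighter(clip=(0.45, 0.55)).fit_transform(
            mortal_panel
        )
        assert table.attrs["n_clipped"] > 0
        assert table["clipped"].sum() == table.attrs["n_clipped"]


class TestDownstreamAgreement:
    def test_null_selection_weighted_fit_matches_unweighted(self):
        cfg = SimConfig(
            n_individuals=1500, seed=13, obs_model=(float(logit(0.75)), 0.0, 0.0)
        )
        panel = simulate_cohort(cfg)
        table = InverseProbabilityWeighter().fit_transform(panel)
        fw = fit_all(panel, weights=table, taus=(0.5,))[0.5]
        fu = fit_all(panel, taus=(0.5,))[0.5]
        assert abs(fw["age"] - fu["age"]) < 5e-4
        assert (fw.coef - fu.coef).abs().max() < 5e-3
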