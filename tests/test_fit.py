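"""Maximum-likelihood fitting: start grid, information criteria, model
comparison, estimator recovery, and the dense-grid global-optimum oracle."""

import numpy as np
import pandas as pd
import pytest

from circmix.estimators import (
    SlotsModel,
    SlotsPlusAveragingModel,
    ThreeComponentModel,
    TwoComponentModel,
)
from circmix.fit import compare_models, fit_mixtur, information_criteria, start_grid
from circmix.models import TrialErrors, negative_log_likelihood
from circmix.simulate import simulate_mixtur


class TestStartGrid:
    def test_sizes(self):
        assert len(start_grid("2_component")) == 9
        assert len(start_grid("3_component")) == 27
        assert len(start_grid("slots")) == 9
        assert len(start_grid("slots_averaging")) == 9

    def test_three_component_contents(self):
        grid = start_grid("3_component")
        assert {"kappa": 10.0, "p_u": 0.4, "p_n": 0.01} in grid
        assert all(g["p_u"] + g["p_n"] <= 1 for g in grid)

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            start_grid("4_component")


class TestInformationCriteria:
    def test_aic_is_penalised_deviance(self):
        assert information_criteria(-100.0, 2, 50)["AIC"] == pytest.approx(204.0)

    def test_small_sample_correction(self):
        out = information_criteria(-100.0, 2, 100)
        assert out["AICc"] == pytest.approx(200 + 4 * (100 / 97))
        assert out["AICc"] == pytest.approx(204.12371, abs=1e-5)
        assert out["BIC"] == pytest.approx(200 + 2 * np.log(100))
        assert out["BIC"] == pytest.approx(209.21034, abs=1e-5)

    def test_aicc_exceeds_aic_and_degenerates(self):
        out = information_criteria(-50.0, 3, 10)
        assert out["AICc"] > out["AIC"]
        assert np.isnan(information_criteria(-50.0, 3, 4)["AICc"])


class TestCompareModels:
    def test_equal_likelihood_gives_penalty_gap(self):
        f2 = {"log_likelihood": -500.0, "n_params": 2, "n_trials": 500}
        f3 = {"log_likelihood": -500.0, "n_params": 3, "n_trials": 500}
        out = compare_models(f2, f3)
        assert out["AIC_difference"] == pytest.approx(-2.0)
        assert out["BIC_difference"] == pytest.approx(-np.log(500))
        assert out["winner_AIC"] == "2_component"
        assert not out["bound_violated"]

    def test_better_three_component_fit(self):
        f2 = {"log_likelihood": -500.0, "n_params": 2, "n_trials": 400}
        f3 = {"log_likelihood": -490.0, "n_params": 3, "n_trials": 400}
        out = compare_models(f2, f3)
        assert out["AIC_difference"] == pytest.approx(18.0)
        assert out["winner_AIC"] == "3_component"

    def test_mismatched_cells_rejected(self):
        f2 = {"log_likelihood": -500.0, "n_params": 2, "n_trials": 400}
        f3 = {"log_likelihood": -490.0, "n_params": 3, "n_trials": 300}
        with pytest.raises(ValueError, match="different trial counts"):
            compare_models(f2, f3)


def _errors_from(table):
    return table.errors()


class TestEstimators:
    def test_two_component_recovers_generating_parameters(self):
        table = simulate_mixtur("2_component", kappa=8.0, p_u=0.1,
                                n_trials=1000, set_size=4, seed=5)
        est = TwoComponentModel().fit(_errors_from(table))
        assert 6.5 <= est.kappa_ <= 9.5
        assert 0.06 <= est.p_u_ <= 0.14
        assert est.p_t_ + est.p_u_ == pytest.approx(1.0, abs=1e-9)

    def test_uniform_data_attributed_to_guessing(self, rng):
        errors = TrialErrors(rng.uniform(-np.pi, np.pi, 10000), np.empty((10000, 0)))
        est = TwoComponentModel().fit(errors)
        assert est.p_u_ >= 0.95

    def test_three_component_recovery_and_weight_sum(self):
        table = simulate_mixtur("3_component", kappa=8.0, p_u=0.1, p_n=0.2,
                                n_trials=2000, set_size=4, seed=6)
        est = ThreeComponentModel().fit(_errors_from(table))
        assert est.p_t_ + est.p_u_ + est.p_n_ == pytest.approx(1.0, abs=1e-9)
        assert abs(est.p_n_ - 0.2) < 0.05
        assert abs(est.kappa_ - 8.0) < 1.5

    def test_nesting_on_identical_data(self):
        table = simulate_mixtur("2_component", kappa=6.0, p_u=0.2,
                                n_trials=400, set_size=4, seed=7)
        err = _errors_from(table)
        ll2 = TwoComponentModel().fit(err).log_likelihood_
        ll3 = ThreeComponentModel().fit(err).log_likelihood_
        assert ll3 >= ll2 - 1e-6

    def test_multistart_dominance(self):
        table = simulate_mixtur("2_component", kappa=4.0, p_u=0.3,
                                n_trials=200, set_size=4, seed=8)
        err = _errors_from(table)
        est = TwoComponentModel().fit(err)
        for start in start_grid("2_component"):
            assert est.nll_ <= negative_log_likelihood(err, "2_component", start) + 1e-9

    def test_matches_dense_grid_oracle(self):
        # the fitted NLL should not exceed the best of an exhaustive 2-D scan
        table = simulate_mixtur("2_component", kappa=5.0, p_u=0.25,
                                n_trials=80, set_size=4, seed=9)
        err = _errors_from(table)
        est = TwoComponentModel().fit(err)
        kappas = np.exp(np.linspace(np.log(0.2), np.log(100), 120))
        p_us = np.linspace(0.0, 0.99, 100)
        grid_best = min(
            negative_log_likelihood(err, "2_component", {"kappa": k, "p_u": p})
            for k in kappas
            for p in p_us
        )
        assert est.nll_ <= grid_best + 1e-6

    def test_sklearn_param_interface(self):
        est = TwoComponentModel(max_iter=500)
        assert est.get_params()["max_iter"] == 500
        est.set_params(tol=1e-6)
        assert est.tol == 1e-6
        import copy

        assert copy.deepcopy(est).get_params() == est.get_params()

    def test_score_matches_negative_nll(self):
        table = simulate_mixtur("2_component", kappa=6.0, p_u=0.1,
                                n_trials=100, set_size=2, seed=10)
        err = _errors_from(table)
        est = TwoComponentModel().fit(err)
        assert est.score(err) == pytest.approx(est.log_likelihood_, abs=1e-8)

    def test_slots_estimator_recovers_capacity(self):
        table = simulate_mixtur("slots", kappa=10.0, K=2.0,
                                n_trials=1500, set_size=4, seed=11)
        err = _errors_from(table)
        est = SlotsModel().fit(err, set_size=4)
        assert abs(est.K_ - 2.0) < 0.4
        assert abs(est.kappa_ - 10.0) < 2.5

    def test_spa_estimator_runs_above_capacity(self):
        table = simulate_mixtur("slots_averaging", kappa=6.0, K=6.0,
                                n_trials=1500, set_size=4, seed=12)
        err = _errors_from(table)
        est = SlotsPlusAveragingModel().fit(err, set_size=4)
        assert est.K_ > 4.0  # spare capacity detected via sharpened precision

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="at least 2 trials"):
            TwoComponentModel().fit(np.array([[0.1]]))


class TestFitMixtur:
    def test_groups_by_set_size(self, small_table):
        fits = fit_mixtur(small_table, model="2_component", return_fit=True)
        assert set(fits["set_size"]) == {2, 4}
        assert {"kappa", "p_t", "p_u", "log_likelihood", "n_trials",
                "AIC", "AICc", "BIC"} <= set(fits.columns)
        assert (fits["n_trials"] == 120).all()

    def test_set_size_one_fixes_swap_weight_at_zero(self):
        table = simulate_mixtur("2_component", kappa=12.0, p_u=0.05,
                                n_trials=150, set_size=1, seed=13)
        fits = fit_mixtur(table, model="3_component")
        assert (fits["p_n"] == 0.0).all()
        two = fit_mixtur(table, model="2_component")
        assert fits["kappa"].iloc[0] == pytest.approx(two["kappa"].iloc[0], rel=1e-4)

    def test_probabilities_sum_to_one(self, small_table):
        fits = fit_mixtur(small_table, model="3_component")
        total = fits["p_t"] + fits["p_u"] + fits["p_n"]
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_missing_group_column_rejected(self, small_table):
        with pytest.raises(ValueError, match="grouping column"):
            fit_mixtur(small_table, model="2_component", group_by=("condition",))

    def test_raw_dataframe_with_custom_columns(self):
        table = simulate_mixtur("2_component", kappa=8.0, p_u=0.1,
                                n_trials=120, set_size=2, seed=14)
        df = table.data.rename(
            columns={"id": "subj", "response": "resp", "target": "tgt",
                     "non_target_1": "foil_1", "set_size": "n_items"}
        )
        fits = fit_mixtur(
            df, model="2_component", unit="radians", id_var="subj",
            response_var="resp", target_var="tgt", non_target_prefix="foil",
            set_size_var="n_items",
        )
        assert len(fits) == 1
        assert 5.0 < fits["kappa"].iloc[0] < 12.0
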