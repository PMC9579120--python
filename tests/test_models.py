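"""Mixture densities: known values against Bessel-series oracles,
normalisation, nesting/reduction identities, and the slots family."""

import numpy as np
import pytest
from scipy.integrate import quad

from circmix.angles import kappa_to_sd, sd_to_kappa
from circmix.models import (
    TrialErrors,
    density_three_component,
    density_two_component,
    negative_log_likelihood,
    slots_density,
    spa_component_kappas,
    spa_density,
)
from oracles import bessel_i_series

TWO_PI = 2 * np.pi


def _single(target_error, *nontarget_errors):
    nte = np.array([nontarget_errors], dtype=float) if nontarget_errors else np.empty((1, 0))
    return TrialErrors(np.array([target_error]), nte)


class TestTwoComponent:
    def test_pure_guessing_is_uniform(self):
        assert density_two_component(_single(1.3), kappa=5.0, p_u=1.0) == pytest.approx(
            1 / TWO_PI
        )

    def test_zero_kappa_is_uniform(self):
        assert density_two_component(_single(0.0), kappa=0.0, p_u=0.0) == pytest.approx(
            1 / TWO_PI
        )

    def test_mode_value_against_bessel_oracle(self):
        # 0.8 * e^8/(2 pi I0(8)) + 0.2/(2 pi)
        expected = 0.8 * np.exp(8) / (TWO_PI * bessel_i_series(0, 8.0)) + 0.2 / TWO_PI
        assert density_two_component(_single(0.0), kappa=8.0, p_u=0.2) == pytest.approx(
            expected, rel=1e-10
        )
        assert expected == pytest.approx(0.91953, abs=1e-5)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            density_two_component(_single(0.0), kappa=1.0, p_u=1.5)


class TestThreeComponent:
    def test_reduces_to_two_component_when_pn_zero(self, rng):
        e = TrialErrors(rng.uniform(-np.pi, np.pi, 50),
                        rng.uniform(-np.pi, np.pi, (50, 3)))
        d3 = density_three_component(e, kappa=4.0, p_u=0.3, p_n=0.0)
        d2 = density_two_component(e, kappa=4.0, p_u=0.3)
        np.testing.assert_allclose(d3, d2, rtol=1e-12)

    def test_pure_swap_at_nontarget_mode(self):
        expected = np.exp(8) / (TWO_PI * bessel_i_series(0, 8.0))
        got = density_three_component(_single(2.0, 0.0), kappa=8.0, p_u=0.0, p_n=1.0)
        assert got == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(1.10962, abs=2e-5)

    def test_normalises_over_responses(self):
        # integrate over the response for a fixed stimulus configuration
        theta, nts = 0.4, np.array([-1.0, 2.0, 2.9])

        def dens(th_hat):
            e = TrialErrors(np.array([th_hat - theta]), (th_hat - nts)[None, :])
            return density_three_component(e, kappa=3.0, p_u=0.15, p_n=0.25)

        total, _ = quad(dens, theta - np.pi, theta + np.pi, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_invariant_to_nontarget_permutation(self, rng):
        te = rng.uniform(-np.pi, np.pi, 20)
        nte = rng.uniform(-np.pi, np.pi, (20, 3))
        d = density_three_component(TrialErrors(te, nte), 5.0, 0.1, 0.2)
        d_perm = density_three_component(
            TrialErrors(te, nte[:, [2, 0, 1]]), 5.0, 0.1, 0.2
        )
        np.testing.assert_allclose(d, d_perm, rtol=1e-12)

    def test_swap_weight_without_nontargets_rejected(self):
        with pytest.raises(ValueError, match="non-target"):
            density_three_component(_single(0.1), kappa=2.0, p_u=0.1, p_n=0.2)


class TestSlotsFamily:
    def test_capacity_reached_is_pure_von_mises(self):
        d = slots_density(_single(0.0), K=4.0, kappa=8.0, set_size=4)
        expected = np.exp(8) / (TWO_PI * bessel_i_series(0, 8.0))
        assert d == pytest.approx(expected, rel=1e-10)

    def test_implied_guess_rate(self):
        # K=2 of 4 items stored -> half the trials are guesses
        d = slots_density(_single(np.pi), K=2.0, kappa=200.0, set_size=4)
        assert d == pytest.approx(0.5 / TWO_PI, rel=1e-6)

    def test_target_rate_scales_with_set_size(self):
        # K=3: all 3 items stored at set size 3; half at set size 6
        p_t_3 = 1 - max(0.0, 1 - 3 / 3)
        p_t_6 = 1 - max(0.0, 1 - 3 / 6)
        assert p_t_3 / p_t_6 == pytest.approx(2.0)

    def test_spa_equals_slots_until_capacity(self):
        e = _single(0.7)
        for N in (4, 5, 8):
            assert spa_density(e, K=3.0, kappa=6.0, set_size=N) == pytest.approx(
                slots_density(e, K=3.0, kappa=6.0, set_size=N), rel=1e-12
            )

    def test_spa_doubling_averages_two_copies(self):
        # K=8, N=4: every item held twice; concentration from sd/sqrt(2)
        kappa = 6.0
        kappa_2 = sd_to_kappa(kappa_to_sd(kappa) / np.sqrt(2))
        e = _single(0.3)
        expected = np.exp(kappa_2 * np.cos(0.3)) / (TWO_PI * bessel_i_series(0, kappa_2))
        assert spa_density(e, K=8.0, kappa=kappa, set_size=4) == pytest.approx(
            expected, rel=1e-8
        )

    def test_spa_peak_sharpens_with_spare_capacity(self):
        e = _single(0.0)
        base = spa_density(e, K=4.0, kappa=6.0, set_size=4)
        averaged = spa_density(e, K=8.0, kappa=6.0, set_size=4)
        assert averaged > base

    def test_spa_component_split_is_continuous_in_K(self):
        m_low, m_high, f_high, k_low, k_high = spa_component_kappas(6.0, 5.0, 4)
        assert (m_low, m_high) == (1, 2)
        assert f_high == pytest.approx(0.5)
        assert k_low == pytest.approx(5.0)
        assert k_high > k_low

    @pytest.mark.parametrize("model, params", [
        ("slots", {"K": 2.5, "kappa": 7.0}),
        ("slots_averaging", {"K": 6.5, "kappa": 7.0}),
    ])
    def test_normalisation(self, model, params):
        from circmix.models import slots_density as sd_, spa_density as spa_

        fn = sd_ if model == "slots" else spa_

        def dens(x):
            return fn(_single(x), set_size=4, **params)

        total, _ = quad(dens, -np.pi, np.pi, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestNegativeLogLikelihood:
    def test_constant_density_single_trial(self):
        nll = negative_log_likelihood(_single(0.3), "2_component",
                                      {"kappa": 1.0, "p_u": 1.0})
        assert nll == pytest.approx(np.log(TWO_PI), abs=1e-12)
        assert nll == pytest.approx(1.83788, abs=1e-5)

    def test_prefers_generating_kappa(self, rng):
        from circmix.angles import vm_sample

        errors = TrialErrors(vm_sample(1000, 0.0, 8.0, rng=rng), np.empty((1000, 0)))
        nll_true = negative_log_likelihood(errors, "2_component", {"kappa": 8.0, "p_u": 0.0})
        nll_off = negative_log_likelihood(errors, "2_component", {"kappa": 2.0, "p_u": 0.0})
        assert nll_true < nll_off

    def test_three_equals_two_at_pn_zero(self, rng):
        e = TrialErrors(rng.uniform(-np.pi, np.pi, 30), rng.uniform(-np.pi, np.pi, (30, 2)))
        p = {"kappa": 5.0, "p_u": 0.2}
        assert negative_log_likelihood(e, "3_component", {**p, "p_n": 0.0}) == pytest.approx(
            negative_log_likelihood(e, "2_component", p), rel=1e-12
        )

    def test_out_of_bounds_params_give_infinity(self):
        assert negative_log_likelihood(_single(0.0), "2_component",
                                       {"kappa": 1.0, "p_u": 1.4}) == np.inf

    @pytest.mark.parametrize("params", [
        {"kappa": 0.7, "p_u": 0.05, "p_n": 0.3},
        {"kappa": 12.0, "p_u": 0.5, "p_n": 0.25},
    ])
    def test_randomised_three_component_normalisation(self, params, rng):
        theta = rng.uniform(-np.pi, np.pi)
        nts = rng.uniform(-np.pi, np.pi, 3)

        def dens(th_hat):
            e = TrialErrors(np.array([th_hat - theta]), (th_hat - nts)[None, :])
            return density_three_component(e, **params)

        total, _ = quad(dens, theta - np.pi, theta + np.pi, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)
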