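"""Likelihood core: forward recursion vs enumeration, priors, derived occupancy."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from occudyn import (
    CovariateSet,
    DynamicOccupancyModel,
    ModelSpec,
    derived_occupancy,
    log_logistic_prior,
    site_log_likelihood,
)
from conftest import constant_covariates, enum_site_loglik, history_from_y


class TestSiteLikelihood:
    def test_two_term_sum(self):
        """T=1, K=1, phi1=0.4, p=0.5, y=0: 0.4*0.5 + 0.6 = 0.8."""
        ll = site_log_likelihood(np.array([[0.0]]), 0.4, 0.3, 0.2, 0.5)
        assert ll == pytest.approx(np.log(0.8), abs=1e-12)

    def test_perfect_detection_gives_phi1(self):
        """T=1, p=1, a detection: the likelihood is exactly phi1."""
        ll = site_log_likelihood(np.array([[1.0, 1.0]]), 0.37, 0.3, 0.2, 1.0)
        assert ll == pytest.approx(np.log(0.37), abs=1e-12)

    def test_impossible_history_is_neg_inf(self):
        """A detection with phi1=0 has probability zero, not an exception."""
        ll = site_log_likelihood(np.array([[1.0]]), 0.0, 0.0, 0.0, 0.5)
        assert ll == -np.inf

    def test_matches_enumeration_t2_k2(self):
        y = np.array([[1.0, 0.0], [0.0, 0.0]])
        ll = site_log_likelihood(y, 0.63, 0.21, 0.34, 0.47)
        assert ll == pytest.approx(enum_site_loglik(y, 0.63, 0.21, 0.34, 0.47), abs=1e-12)

    def test_matches_enumeration_random(self):
        """Forward recursion equals brute-force enumeration, T<=4, with NAs."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            t = rng.integers(1, 5)
            k = rng.integers(1, 4)
            y = (rng.random((t, k)) < 0.4).astype(float)
            y[rng.random((t, k)) < 0.25] = np.nan
            phi1 = rng.random()
            gamma = rng.random(max(t - 1, 1))
            eps = rng.random(max(t - 1, 1))
            p = rng.random((t, k))
            got = site_log_likelihood(y, phi1, gamma, eps, p)
            want = enum_site_loglik(y, phi1, gamma, eps, p)
            if np.isfinite(want):
                assert got == pytest.approx(want, abs=1e-10)
            else:
                assert got == -np.inf

    def test_normalization_over_histories(self):
        """Sum of likelihoods over all 2^(T*K) histories equals 1 (T=K=2)."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            phi1, gamma, eps = rng.random(3)
            p = rng.random((2, 2))
            total = 0.0
            for bits in itertools.product([0, 1], repeat=4):
                y = np.array(bits, dtype=float).reshape(2, 2)
                total += np.exp(site_log_likelihood(y, phi1, gamma, eps, p))
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_na_equals_marginalization(self):
        """An NA occasion contributes a factor 1: same likelihood as dropping it."""
        phi1, gamma, eps, p = 0.55, 0.25, 0.15, 0.4
        y_na = np.array([[1.0, np.nan], [0.0, 0.0]])
        ll_na = site_log_likelihood(y_na, phi1, gamma, eps, p)
        # same model with that occasion removed: K differs per season, so pad
        # season 2 with NA too and compare against a 1-occasion first season
        y_small = np.array([[1.0], [0.0]])
        p_small = np.full((2, 1), p)
        ll_small = (
            site_log_likelihood(np.array([[1.0, np.nan], [0.0, np.nan]]), phi1, gamma, eps, p)
        )
        assert site_log_likelihood(y_small, phi1, gamma, eps, p_small) == pytest.approx(
            ll_small, abs=1e-12
        )
        assert ll_na == pytest.approx(
            enum_site_loglik(y_na, phi1, gamma, eps, p), abs=1e-12
        )

    def test_all_na_season_keeps_site(self):
        """A fully NA season is marginalized; other seasons still inform."""
        y = np.array([[np.nan, np.nan], [1.0, 0.0]])
        ll = site_log_likelihood(y, 0.5, 0.3, 0.2, 0.6)
        assert np.isfinite(ll)
        assert ll == pytest.approx(enum_site_loglik(y, 0.5, 0.3, 0.2, 0.6), abs=1e-12)

    def test_monotone_in_phi1_for_empty_history(self):
        y = np.zeros((2, 3))
        lls = [site_log_likelihood(y, phi1, 0.2, 0.3, 0.4) for phi1 in np.linspace(0.01, 0.99, 25)]
        assert all(a >= b - 1e-12 for a, b in zip(lls, lls[1:]))


class TestModelMatrices:
    def _simple_model(self, spec=None, n=4, t=3, k=2):
        rng = np.random.default_rng(0)
        y = (rng.random((n, t, k)) < 0.4).astype(float)
        hist = history_from_y(y)
        labels = hist.design.season_labels
        covs = CovariateSet(
            site=pd.DataFrame(
                {
                    "TPROD": rng.normal(size=n),
                    "Feat": ["none", "trail", "dirt road", "none"],
                }
            ),
            season_site={"NDVI": pd.DataFrame(rng.normal(size=(n, t)), columns=labels)},
            categorical_levels={"Feat": ["none", "trail", "dirt road"]},
            is_standardized=True,
        )
        return DynamicOccupancyModel(hist, covs, spec or ModelSpec())

    def test_zero_coefficients_give_half(self):
        m = self._simple_model()
        pr = m.linear_predictors(np.zeros(m.k_params))
        for arr in pr.values():
            np.testing.assert_allclose(arr, 0.5)

    def test_large_negative_intercept_drives_probability_to_zero(self):
        m = self._simple_model()
        probs = []
        for b0 in (0.0, -2.0, -6.0, -20.0):
            theta = np.zeros(m.k_params)
            theta[0] = b0
            probs.append(m.linear_predictors(theta)["phi1"][0])
        assert all(a > b for a, b in zip(probs, probs[1:]))
        assert probs[-1] < 1e-8

    def test_slope_inverse_logit(self):
        """Slope 0.51 at standardized value +1, zero intercept: p = expit(0.51)."""
        spec = ModelSpec(phi1_terms=("TPROD",))
        m = self._simple_model(spec)
        theta = np.zeros(m.k_params)
        theta[m.param_names.index("phi1[TPROD]")] = 0.51
        x = m.covariates.site["TPROD"].to_numpy()
        got = m.linear_predictors(theta)["phi1"]
        np.testing.assert_allclose(got, expit(0.51 * x))
        assert expit(0.51) == pytest.approx(0.625, abs=0.001)

    def test_categorical_reference_coding(self):
        spec = ModelSpec(p_terms=("Season", "Feat"))
        m = self._simple_model(spec)
        assert "p[Season:S1]" in m.param_names
        assert "p[Feat:trail]" in m.param_names
        assert "p[Feat:none]" not in m.param_names
        # reference site (Feat=none), first season: p = expit(intercept)
        theta = np.zeros(m.k_params)
        theta[m.param_names.index("p[Feat:trail]")] = 1.5
        p = m.linear_predictors(theta)["p"]
        assert p[0, 0, 0] == pytest.approx(0.5)
        assert p[1, 0, 0] == pytest.approx(expit(1.5))

    def test_unknown_covariate_errors(self):
        with pytest.raises(KeyError, match="mystery"):
            self._simple_model(ModelSpec(phi1_terms=("mystery",)))

    def test_transition_alignment_next_season(self):
        """Transition t -> t+1 reads the season-site value of season t+1."""
        spec = ModelSpec(gamma_terms=("NDVI",))
        m = self._simple_model(spec)
        theta = np.zeros(m.k_params)
        theta[m.param_names.index("gamma[NDVI]")] = 1.0
        vals = m.covariates.season_site["NDVI"].to_numpy()
        got = m.linear_predictors(theta)["gamma"]
        np.testing.assert_allclose(got, expit(vals[:, 1:]))


class TestPointwise:
    def test_single_site_and_permutation(self):
        rng = np.random.default_rng(2)
        y = (rng.random((5, 2, 3)) < 0.3).astype(float)
        hist = history_from_y(y)
        covs = constant_covariates(5, hist.design.season_labels)
        m = DynamicOccupancyModel(hist, covs, ModelSpec())
        theta = rng.normal(size=m.k_params)
        vec = m.loglikeobs(theta)
        assert m.loglike(theta) == pytest.approx(vec.sum())
        perm = rng.permutation(5)
        hist_p = history_from_y(y[perm])
        m_p = DynamicOccupancyModel(hist_p, covs, ModelSpec())
        np.testing.assert_allclose(m_p.loglikeobs(theta), vec[perm], atol=1e-12)


class TestDerivedOccupancy:
    def test_absorbing_dynamics_constant(self):
        phi = derived_occupancy(np.array([0.7]), np.zeros((1, 3)), np.zeros((1, 3)))
        np.testing.assert_allclose(phi, 0.7)

    def test_one_step(self):
        phi = derived_occupancy(np.array([0.5]), np.full((1, 1), 0.3), np.full((1, 1), 0.2))
        assert phi[0, 1] == pytest.approx(0.55)

    def test_stationary_point(self):
        """gamma = eps*phi/(1-phi): phi=0.4, eps=0.3 -> gamma=0.2 keeps phi at 0.4."""
        phi = derived_occupancy(np.array([0.4]), np.full((1, 3), 0.2), np.full((1, 3), 0.3))
        np.testing.assert_allclose(phi, 0.4)


class TestPrior:
    def test_density_at_zero(self):
        assert log_logistic_prior(np.array([0.0])) == pytest.approx(np.log(0.25))

    def test_symmetric(self):
        theta = np.array([0.7, -1.3, 2.2])
        assert log_logistic_prior(theta) == pytest.approx(log_logistic_prior(-theta))

    def test_independent_sum(self):
        assert log_logistic_prior(np.zeros(2)) == pytest.approx(2 * np.log(0.25))


class TestModelSpecRules:
    def test_univariate_rule(self):
        with pytest.raises(ValueError, match="univariate"):
            ModelSpec(phi1_terms=("a", "b"))

    def test_gamma_eps_exclusion(self):
        with pytest.raises(ValueError, match="simultaneously"):
            ModelSpec(gamma_terms=("NDVI",), eps_terms=("Graz",))

    def test_roundtrip_dict(self):
        spec = ModelSpec(phi1_terms=("TPROD",), p_terms=("Season", "Feat"), species="fox")
        assert ModelSpec.from_dict(spec.to_dict()) == spec
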