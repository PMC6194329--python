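import dataclasses

import numpy as np
import pytest

from trophimix import mixing
from trophimix.mixing import (
    MixingProblem,
    PriorSpec,
    calibrate_prior,
    combine_sources,
    compare_models,
    fit_mixing_model,
    source_correlation_check,
)


def _problem(mu, p_true=None, n=40, om=0.5, resid=0.3, alpha=None, seed=0, x=None):
    mu = np.asarray(mu, dtype=float)
    K = mu.shape[0]
    om_arr = np.full((K, 2), om)
    if x is None:
        rng = np.random.default_rng(seed)
        s = rng.normal(mu[None], om_arr[None], size=(n, K, 2))
        x = np.einsum("k,nkj->nj", np.asarray(p_true), s) + rng.normal(0, resid, (n, 2))
    return MixingProblem(
        consumers=x,
        source_names=[f"S{k}" for k in range(K)],
        source_means=mu,
        source_sds=om_arr,
        tdf_means=np.zeros(2),
        tdf_sds=np.zeros(2),
        prior_alpha=np.ones(K) if alpha is None else np.asarray(alpha),
    )


WELL_SEPARATED = np.array([[-18.0, 8.0], [-12.0, 10.0], [-15.0, 15.0]])


class TestCalibratePrior:
    def test_closed_form_uniform_k5(self):
        spec = calibrate_prior(np.full(5, 0.2), target_se=0.078)
        assert spec.alpha0 == pytest.approx(0.2 * 0.8 / 0.078**2 - 1, rel=1e-12)
        assert spec.alpha0 == pytest.approx(25.3, abs=0.05)

    def test_implied_sd_of_largest_component_hits_target(self):
        m = np.array([0.5, 0.3, 0.15, 0.05])
        spec = calibrate_prior(m, target_se=0.078)
        mmax = m.max()
        sd = np.sqrt(mmax * (1 - mmax) / (spec.alpha0 + 1))
        assert sd == pytest.approx(0.078, abs=1e-6)

    def test_larger_se_gives_vaguer_prior(self):
        m = np.full(4, 0.25)
        a_small = calibrate_prior(m, target_se=0.05).alpha0
        a_big = calibrate_prior(m, target_se=0.15).alpha0
        assert a_big < a_small

    def test_flat_prior_is_all_ones(self):
        spec = PriorSpec.flat(6)
        np.testing.assert_array_equal(spec.alpha, np.ones(6))

    def test_zero_component_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            spec = calibrate_prior(np.array([0.7, 0.3, 0.0]))
        assert (spec.alpha > 0).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            calibrate_prior(np.array([0.5, 0.4]))  # not a simplex
        with pytest.raises(ValueError):
            calibrate_prior(np.full(4, 0.25), target_se=0.6)


class TestFitMixingModel:
    def test_exactly_identified_midpoint_mixture(self):
        mu = np.array([[-18.0, 8.0], [-12.0, 12.0]])
        x = np.tile(mu.mean(axis=0), (30, 1)) + np.random.default_rng(3).normal(0, 0.05, (30, 2))
        prob = _problem(mu, om=0.0, x=x)
        summ = fit_mixing_model(prob, n_iter=6000, n_chains=4, seed=1)
        np.testing.assert_allclose(summ.mean, [0.5, 0.5], atol=0.02)

    def test_vertex_case_consumers_at_source_one(self):
        mu = np.array([[-18.0, 8.0], [-12.0, 12.0]])
        x = np.tile(mu[0], (30, 1)) + np.random.default_rng(4).normal(0, 0.05, (30, 2))
        prob = _problem(mu, om=0.0, x=x)
        summ = fit_mixing_model(prob, n_iter=6000, n_chains=4, seed=2)
        assert summ.mean[0] > 0.95

    def test_two_source_one_isotope_mass_balance(self):
        # noise-free, second isotope carries no information (identical means)
        mu = np.array([[-18.0, 10.0], [-12.0, 10.0]])
        x_val = -13.5
        p1 = (x_val - mu[1, 0]) / (mu[0, 0] - mu[1, 0])  # closed-form solution
        x = np.tile([x_val, 10.0], (40, 1)) + np.random.default_rng(5).normal(0, 0.02, (40, 2))
        prob = _problem(mu, om=0.0, x=x)
        summ = fit_mixing_model(prob, n_iter=8000, n_chains=4, seed=3)
        assert summ.mean[0] == pytest.approx(p1, abs=0.02)

    def test_parameter_recovery_with_flat_prior(self):
        p_true = np.array([0.6, 0.3, 0.1])
        prob = _problem(WELL_SEPARATED, p_true=p_true, n=50, seed=11)
        summ = fit_mixing_model(prob, n_iter=10_000, n_chains=4, seed=11)
        assert summ.converged
        np.testing.assert_allclose(summ.mean, p_true, atol=0.10)
        assert (summ.ci_low <= summ.midvalue).all()
        assert (summ.midvalue <= summ.ci_high).all()

    def test_draws_on_simplex(self):
        prob = _problem(WELL_SEPARATED, p_true=[0.5, 0.3, 0.2], n=20, seed=6)
        summ = fit_mixing_model(prob, n_iter=2000, n_chains=2, seed=6)
        np.testing.assert_allclose(summ.draws.sum(axis=1), 1.0, atol=1e-12)
        assert (summ.draws >= 0).all()

    def test_prior_dominance_limit(self):
        """With a very concentrated prior the posterior mean approaches the
        prior mean; with n large and a flat prior it approaches the truth."""
        p_true = np.array([0.6, 0.3, 0.1])
        prior_mean = np.array([0.2, 0.3, 0.5])
        strong = _problem(WELL_SEPARATED, p_true=p_true, n=10, seed=8,
                          alpha=prior_mean * 50_000)
        summ_strong = fit_mixing_model(strong, n_iter=8000, n_chains=4, seed=8)
        np.testing.assert_allclose(summ_strong.mean, prior_mean, atol=0.05)

        big = _problem(WELL_SEPARATED, p_true=p_true, n=150, seed=9)
        summ_big = fit_mixing_model(big, n_iter=8000, n_chains=4, seed=9)
        small = _problem(WELL_SEPARATED, p_true=p_true, n=15, seed=9)
        summ_small = fit_mixing_model(small, n_iter=8000, n_chains=4, seed=9)
        err_big = np.abs(summ_big.mean - p_true).sum()
        err_small = np.abs(summ_small.mean - p_true).sum()
        assert err_big < 0.08
        assert err_big < err_small + 0.02

    def test_seed_invariance_within_monte_carlo_error(self):
        prob = _problem(WELL_SEPARATED, p_true=[0.5, 0.3, 0.2], n=40, seed=10)
        s1 = fit_mixing_model(prob, n_iter=6000, n_chains=4, seed=1)
        s2 = fit_mixing_model(prob, n_iter=6000, n_chains=4, seed=2)
        np.testing.assert_allclose(s1.mean, s2.mean, atol=0.03)

    def test_acceptance_rate_in_adapted_band(self):
        prob = _problem(WELL_SEPARATED, p_true=[0.5, 0.3, 0.2], n=40, seed=12)
        summ = fit_mixing_model(prob, n_iter=6000, n_chains=4, seed=4)
        assert 0.15 <= summ.accept_rate <= 0.45


class TestDiagnosticsAndCombination:
    def test_identical_sources_flagged_as_confounded(self):
        mu = np.array([[-15.0, 10.0], [-15.0, 10.0], [-10.0, 14.0]])
        prob = _problem(mu, p_true=[0.4, 0.4, 0.2], n=40, seed=13)
        with np.errstate(all="ignore"):
            summ = fit_mixing_model(prob, n_iter=6000, n_chains=4, seed=5)
        corr, flagged = source_correlation_check(summ)
        assert ("S0", "S1") in flagged
        # flagging is symmetric by construction of the pair list
        assert np.allclose(corr.to_numpy(), corr.to_numpy().T)

    def test_well_separated_sources_not_flagged(self):
        prob = _problem(WELL_SEPARATED, p_true=[0.5, 0.3, 0.2], n=40, seed=14)
        summ = fit_mixing_model(prob, n_iter=6000, n_chains=4, seed=6)
        _, flagged = source_correlation_check(summ)
        assert flagged == []

    def test_combining_identical_sources_preserves_moments(self):
        mu = np.array([[-15.0, 10.0], [-15.0, 10.0], [-10.0, 14.0]])
        prob = _problem(mu, p_true=[0.4, 0.4, 0.2], n=20, seed=15, alpha=[2.0, 2.0, 1.0])
        merged = combine_sources(prob, [["S0", "S1"]])
        assert merged.source_names[0] == "S0 + S1"
        np.testing.assert_allclose(merged.source_means[0], mu[0])
        np.testing.assert_allclose(merged.source_sds[0], prob.source_sds[0])
        assert merged.prior_alpha[0] == pytest.approx(4.0)
        # total prior concentration conserved
        assert merged.prior_alpha.sum() == pytest.approx(prob.prior_alpha.sum())

    def test_merged_model_resolves_confounded_pair(self):
        mu = np.array([[-15.0, 10.0], [-15.0, 10.0], [-10.0, 14.0]])
        p_true = [0.4, 0.4, 0.2]
        prob = _problem(mu, p_true=p_true, n=50, seed=16)
        merged = combine_sources(prob, [["S0", "S1"]])
        summ = fit_mixing_model(merged, n_iter=8000, n_chains=4, seed=7)
        assert summ.converged
        assert summ.mean[0] == pytest.approx(0.8, abs=0.08)
        assert (summ.ci_high[0] - summ.ci_low[0]) < 0.2  # tight combined posterior

    def test_singleton_group_is_identity(self):
        prob = _problem(WELL_SEPARATED, p_true=[0.5, 0.3, 0.2], n=10, seed=17)
        same = combine_sources(prob, [["S0"]])
        assert same.source_names == prob.source_names
        np.testing.assert_allclose(same.source_means, prob.source_means)


class TestCompareModels:
    def test_identical_summaries_full_overlap(self):
        prob = _problem(WELL_SEPARATED, p_true=[0.5, 0.3, 0.2], n=30, seed=18)
        summ = fit_mixing_model(prob, n_iter=4000, n_chains=2, seed=8)
        r = compare_models(summ, summ)
        assert r.index == pytest.approx(1.0)

    def test_strong_data_with_without_prior_overlap(self):
        p_true = np.array([0.6, 0.3, 0.1])
        prob_flat = _problem(WELL_SEPARATED, p_true=p_true, n=100, seed=19)
        prior = mixing.calibrate_prior(np.array([0.55, 0.35, 0.10]))
        prob_prior = dataclasses.replace(prob_flat, prior_alpha=prior.alpha)
        s_flat = fit_mixing_model(prob_flat, n_iter=6000, n_chains=4, seed=9)
        s_prior = fit_mixing_model(prob_prior, n_iter=6000, n_chains=4, seed=10)
        r = compare_models(s_prior, s_flat)
        assert r.significant_overlap
        assert compare_models(s_flat, s_prior).index == pytest.approx(r.index)

    def test_mismatched_sources_rejected(self):
        prob = _problem(WELL_SEPARATED, p_true=[0.5, 0.3, 0.2], n=10, seed=20)
        summ = fit_mixing_model(prob, n_iter=2000, n_chains=2, seed=11)
        other = dataclasses.replace(summ, source_names=["X", "Y", "Z"])
        with pytest.raises(ValueError, match="different source sets"):
            compare_models(summ, other)
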