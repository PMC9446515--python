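"""MCMC correctness against deterministic quadrature oracles, and the
posterior decision quantities."""

import numpy as np
import pytest
from scipy.special import expit, logit

from conftest import hier_oracle_means, indep_oracle_mean
from platformsim.design_core import McmcSettings, TrialData, rng_stream
from platformsim.posterior_models import (
    PosteriorDraws,
    fit_drift,
    fit_hierarchical,
    fit_independent,
    fit_model,
    mcse_mean,
    posterior_variance,
    prob_or_in_band,
    prob_superiority,
)


def _cell_data(pairs):
    """TrialData with K=1 from a list of (y, n) pairs."""
    ys, ns = zip(*pairs)
    n = np.array(ns, dtype=float)[:, None, None]
    y = np.array(ys, dtype=float)[:, None, None]
    return TrialData(n, y)


def _draws_from_p(p):
    """Wrap a raw (n_draws, J, K) array as PosteriorDraws for the ops."""
    return PosteriorDraws(model_kind="independent", p=np.asarray(p, dtype=float))


class TestIndependentModel:
    def test_matches_quadrature_oracle(self, std_mcmc):
        data = TrialData(np.array([[[10.0]]]), np.array([[[3.0]]]))
        draws = fit_independent(data, std_mcmc, rng_stream(5, 0))
        chain = draws.p[:, 0, 0]
        oracle = indep_oracle_mean(3, 10)
        assert abs(chain.mean() - oracle) < 3 * mcse_mean(chain)

    def test_no_data_prior_is_symmetric(self, std_mcmc):
        data = TrialData(np.zeros((2, 2, 1)), np.zeros((2, 2, 1)))
        draws = fit_independent(data, std_mcmc, rng_stream(8, 0))
        med = np.median(draws.p, axis=0)
        np.testing.assert_allclose(med, 0.5, atol=0.03)

    def test_identical_cells_are_exchangeable(self, std_mcmc):
        n = np.full((2, 1, 1), 20.0)
        y = np.full((2, 1, 1), 7.0)
        draws = fit_independent(TrialData(n, y), std_mcmc, rng_stream(9, 0))
        m0, m1 = draws.p[:, 0, 0].mean(), draws.p[:, 1, 0].mean()
        tol = 3 * (mcse_mean(draws.p[:, 0, 0]) + mcse_mean(draws.p[:, 1, 0]))
        assert abs(m0 - m1) < tol

    def test_invalid_mcmc_rejected(self):
        with pytest.raises(ValueError):
            McmcSettings(n_iter=10, n_burn=10)


class TestHierarchicalModel:
    def test_matches_quadrature_oracle(self, std_mcmc):
        data = _cell_data([(1, 3), (2, 3)])
        draws = fit_hierarchical(data, m=1.0, mcmc=std_mcmc, stream=rng_stream(6, 0))
        oracle_means, oracle_pk = hier_oracle_means([1, 2], [3, 3], m=1.0)
        for j in range(2):
            chain = draws.p[:, j, 0]
            assert abs(chain.mean() - oracle_means[j]) < 3 * mcse_mean(chain)
        pk_chain = draws.hypermean[:, 0]
        assert abs(pk_chain.mean() - oracle_pk) < 3 * mcse_mean(pk_chain)

    def test_no_data_prior_mean_half(self, std_mcmc):
        data = TrialData(np.zeros((3, 2, 1)), np.zeros((3, 2, 1)))
        draws = fit_hierarchical(data, m=5.0, mcmc=std_mcmc, stream=rng_stream(10, 0))
        np.testing.assert_allclose(draws.p.mean(axis=0), 0.5, atol=0.03)

    def test_shrinkage_monotone_in_m(self, fast_mcmc):
        """Average |posterior mean of P_jk - posterior mean of P_k| shrinks
        as the borrowing strength m grows."""
        rng = np.random.default_rng(3)
        n = np.full((5, 2, 1), 60.0)
        truth = np.array([0.1, 0.3, 0.5, 0.6, 0.8])
        y = rng.binomial(60, truth[:, None, None], size=(5, 2, 1)).astype(float)
        data = TrialData(n, y)
        deviations = []
        for i, m in enumerate((1.0, 10.0, 20.0, 30.0)):
            draws = fit_hierarchical(data, m=m, mcmc=fast_mcmc,
                                     stream=rng_stream(20, i))
            dev = np.abs(draws.p.mean(axis=0)
                         - draws.hypermean.mean(axis=0)[None, :]).mean()
            deviations.append(dev)
        assert np.all(np.diff(deviations) < 0.01)  # non-increasing up to MC noise
        assert deviations[-1] < deviations[0]

    def test_spread_shrinks_at_extreme_m(self, fast_mcmc):
        data = _cell_data([(1, 3), (2, 3)])
        means = {}
        for m in (1.0, 1000.0):
            draws = fit_hierarchical(data, m=m, mcmc=fast_mcmc,
                                     stream=rng_stream(21, int(m)))
            p = draws.p.mean(axis=0)[:, 0]
            means[m] = p.max() - p.min()
        assert means[1000.0] < means[1.0]

    def test_credible_interval_coverage_at_nominal_rate(self, fast_mcmc):
        """Simulating from the hierarchical model, 95% intervals for P_jk
        cover the simulated truth at close to the nominal rate."""
        m, n_per_cell, n_reps = 10.0, 500, 200
        rng = np.random.default_rng(2024)
        covered = total = 0
        for rep in range(n_reps):
            pk = rng.beta(1, 1, size=2)
            pjk = rng.beta(m * pk, m * (1 - pk), size=(3, 2))
            y = rng.binomial(n_per_cell, pjk).astype(float)
            data = TrialData(np.full((3, 2, 1), float(n_per_cell)), y[:, :, None])
            draws = fit_hierarchical(data, m=m, mcmc=fast_mcmc,
                                     stream=rng_stream(30, rep))
            lo = np.quantile(draws.p, 0.025, axis=0)
            hi = np.quantile(draws.p, 0.975, axis=0)
            covered += np.sum((lo <= pjk) & (pjk <= hi))
            total += pjk.size
        coverage = covered / total
        assert 0.92 <= coverage <= 0.985


class TestDriftModel:
    def test_single_period_reduces_to_hierarchical(self, std_mcmc):
        data = _cell_data([(1, 3), (2, 3)])
        h = fit_hierarchical(data, m=1.0, mcmc=std_mcmc, stream=rng_stream(6, 1))
        d = fit_drift(data, m=1.0, mcmc=std_mcmc, stream=rng_stream(7, 0))
        assert d.theta.shape[1] == 0
        assert np.all(d.tau > 0)
        for j in range(2):
            tol = 3 * (mcse_mean(h.p[:, j, 0]) + mcse_mean(d.p[:, j, 0]))
            assert abs(h.p[:, j, 0].mean() - d.p[:, j, 0].mean()) < tol

    def test_recovers_linear_drift_profile(self, std_mcmc):
        """Posterior means of theta recover the simulated linear profile
        (0.75, 0.5, 0.25, 0) at large per-cell sample sizes."""
        theta_true = np.array([0.75, 0.5, 0.25, 0.0])
        n_cell = 2000
        rng = np.random.default_rng(42)
        pT = np.full((2, 2), 0.5)
        n3 = np.full((2, 2, 4), float(n_cell))
        y3 = np.empty((2, 2, 4))
        for t in range(4):
            y3[:, :, t] = rng.binomial(n_cell, expit(logit(pT) + theta_true[t]))
        draws = fit_drift(TrialData(n3, y3), m=30.0, mcmc=std_mcmc,
                          stream=rng_stream(11, 0))
        # simulation error: binomial noise on the logit scale, pooled over
        # 4 cells, roughly 1/sqrt(4 * n p (1-p)) per period pair
        sim_err = 2.0 / np.sqrt(4 * n_cell * 0.25)
        for t in range(3):
            chain = draws.theta[:, t]
            tol = 3 * (mcse_mean(chain) + sim_err)
            assert abs(chain.mean() - theta_true[t]) < tol

    def test_theta_intervals_cover_zero_without_drift(self, fast_mcmc):
        """With all periods generated at identical rates, theta credible
        intervals cover 0 at close to the nominal rate."""
        rng = np.random.default_rng(7)
        covered = total = 0
        for rep in range(30):
            y3 = rng.binomial(400, 0.5, size=(2, 2, 3)).astype(float)
            data = TrialData(np.full((2, 2, 3), 400.0), y3)
            draws = fit_drift(data, m=10.0, mcmc=fast_mcmc,
                              stream=rng_stream(40, rep))
            lo = np.quantile(draws.theta, 0.025, axis=0)
            hi = np.quantile(draws.theta, 0.975, axis=0)
            covered += np.sum((lo <= 0) & (0 <= hi))
            total += draws.theta.shape[1]
        assert covered / total >= 0.88

    def test_dispatch(self, tiny_mcmc):
        data = _cell_data([(1, 3), (2, 3)])
        for kind in ("independent", "hierarchical", "hierarchical_drift"):
            draws = fit_model(kind, data, 5.0, tiny_mcmc, rng_stream(50, 0))
            assert draws.model_kind == kind
        with pytest.raises(ValueError):
            fit_model("bogus", data, 5.0, tiny_mcmc, rng_stream(50, 1))


class TestDrawInvariants:
    def test_probabilities_strictly_inside_unit_interval(self, fast_mcmc):
        data = _cell_data([(0, 5), (5, 5)])
        draws = fit_hierarchical(data, m=2.0, mcmc=fast_mcmc, stream=rng_stream(60, 0))
        assert np.all(draws.p > 0) and np.all(draws.p < 1)
        assert np.all(draws.hypermean > 0) and np.all(draws.hypermean < 1)
        assert draws.n_draws == fast_mcmc.n_draws

    def test_flat_table_export(self, tiny_mcmc):
        data = TrialData(np.full((2, 2, 2), 10.0), np.full((2, 2, 2), 4.0))
        draws = fit_drift(data, m=5.0, mcmc=tiny_mcmc, stream=rng_stream(61, 0))
        table = draws.to_table()
        assert set(table.columns) == {"draw", "chain", "parameter", "value"}
        # p cells + hypermeans + thetas + tau
        assert table["parameter"].nunique() == 4 + 2 + 1 + 1


class TestDecisionQuantities:
    def test_prob_superiority_enumeration(self):
        p = np.zeros((3, 1, 2))
        p[:, 0, 1] = [0.3, 0.5, 0.7]  # EVT
        p[:, 0, 0] = [0.2, 0.6, 0.6]  # MM
        draws = _draws_from_p(p)
        assert prob_superiority(draws, 0, 1, 0) == pytest.approx(2 / 3)
        assert prob_superiority(draws, 0, 0, 1) == pytest.approx(1 / 3)

    def test_ties_count_as_not_superior(self):
        p = np.full((4, 1, 2), 0.4)
        assert prob_superiority(_draws_from_p(p), 0, 1, 0) == 0.0

    def test_complementarity_without_ties(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.01, 0.99, size=(500, 2, 2))
        draws = _draws_from_p(p)
        for j in range(2):
            assert prob_superiority(draws, j, 0, 1) + prob_superiority(draws, j, 1, 0) == 1.0

    def test_same_arm_rejected(self):
        with pytest.raises(ValueError):
            prob_superiority(_draws_from_p(np.full((2, 1, 2), 0.5)), 0, 1, 1)

    def test_or_identity_draw_inside_band(self):
        p = np.full((1, 1, 2), 0.5)
        assert prob_or_in_band(_draws_from_p(p), 0) == 1.0

    def test_or_formula_hand_computed(self):
        # MM 0.7, EVT 0.35 -> OR = (0.7/0.3)/(0.35/0.65) = 13/3 outside (0.8, 1.2)
        p = np.array([[[0.7, 0.35]]])
        assert prob_or_in_band(_draws_from_p(p), 0) == 0.0

    def test_or_band_odds_symmetry(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.05, 0.95, size=(400, 1, 2))
        direct = prob_or_in_band(_draws_from_p(p), 0, 0.8, 1.2)
        flipped = prob_or_in_band(_draws_from_p(1 - p), 0, 1 / 1.2, 1 / 0.8)
        assert direct == pytest.approx(flipped)

    def test_posterior_variance(self):
        p = np.array([[[0.2, 0.5]], [[0.4, 0.5]]])
        draws = _draws_from_p(p)
        assert posterior_variance(draws, 0, 0) == pytest.approx(0.02)
        assert posterior_variance(draws, 0, 1) == 0.0

    def test_variance_symmetric_under_complement(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, size=(100, 1, 2))
        v1 = posterior_variance(_draws_from_p(p), 0, 0)
        v2 = posterior_variance(_draws_from_p(1 - p), 0, 0)
        assert v1 == pytest.approx(v2)
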