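"""EM algorithm: initialization, M-step, likelihood, convergence, K selection."""

import numpy as np
import pytest

from mixnets.data_model import Dag
from mixnets.em import (FitConfig, MixtureModel, component_loglik, e_step,
                        fit, information_criteria, init_memberships,
                        log_parameter_prior, m_step_params, select_k)
from mixnets.evaluation import ari
from mixnets.simulate import SimulationConfig, generate_mixture

from conftest import make_dataset


class TestInitMemberships:
    def test_soft_weight_pattern(self, rng):
        x = np.vstack([rng.normal(0, 1, (20, 4)), rng.normal(4, 1, (20, 4)),
                       rng.normal(-4, 1, (20, 4))])
        ds = make_dataset(x)
        mem = init_memberships(ds, 3, 0)
        assert mem.gamma.shape == (60, 3)
        # each row is a permutation of (0.6, 0.2, 0.2)
        assert np.allclose(np.sort(mem.gamma, axis=1),
                           [0.2, 0.2, 0.6])
        assert np.allclose(mem.gamma.sum(axis=1), 1.0)

    def test_k1_degenerate(self, rng):
        ds = make_dataset(rng.normal(size=(10, 3)))
        mem = init_memberships(ds, 1, 0)
        assert np.allclose(mem.gamma, 1.0)

    def test_separated_blobs_recovered(self, rng):
        x = np.vstack([rng.normal(0, 1, (25, 5)), rng.normal(6, 1, (25, 5))])
        ds = make_dataset(x)
        mem = init_memberships(ds, 2, 0)
        truth = np.array([0] * 25 + [1] * 25)
        assert ari(mem.hard, truth) == 1.0


class TestMStep:
    def test_binary_pseudocount(self):
        col = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], dtype=float)
        ds = make_dataset(col[:, None], n_b=1)
        params = m_step_params(ds, np.ones(10), Dag(1, discrete=[0]))
        assert params.lam[0] == pytest.approx(5 / 12)

    def test_parentless_mean_is_weighted_mean(self, rng):
        x = rng.normal(2.0, 1.0, size=(50, 1))
        ds = make_dataset(x)
        params = m_step_params(ds, np.ones(50), Dag(1))
        assert params.m[0] == pytest.approx(x.mean(), abs=1e-9)

    def test_regression_recovers_noiseless_slope(self, rng):
        x0 = rng.normal(size=(200,))
        x = np.column_stack([x0, 2.0 * x0])
        ds = make_dataset(x)
        params = m_step_params(ds, np.ones(200), Dag(2, [(0, 1)]),
                               estimator="mle")
        assert params.beta[1][0] == pytest.approx(2.0, abs=1e-3)
        # ridge (MAP) estimate shrinks toward but stays near 2
        pmap = m_step_params(ds, np.ones(200), Dag(2, [(0, 1)]))
        assert pmap.beta[1][0] == pytest.approx(2.0, abs=0.05)

    def test_empty_cluster_rejected(self, rng):
        ds = make_dataset(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            m_step_params(ds, np.zeros(5), Dag(2))


class TestComponentLoglik:
    def test_symmetric_bernoulli(self):
        ds = make_dataset(np.array([[1.0]]), n_b=1)
        from mixnets.em import ComponentParams
        params = ComponentParams({0: 0.5}, {}, {}, {})
        ll = component_loglik(ds, Dag(1, discrete=[0]), params)
        assert ll[0] == pytest.approx(np.log(0.5))

    def test_standard_normal_at_mean(self):
        ds = make_dataset(np.array([[0.0]]))
        from mixnets.em import ComponentParams
        params = ComponentParams({}, {0: 0.0}, {0: 1.0}, {})
        ll = component_loglik(ds, Dag(1), params)
        assert ll[0] == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_conditional_mean_hit_exactly(self):
        ds = make_dataset(np.array([[2.0, 2.0]]))
        from mixnets.em import ComponentParams
        params = ComponentParams({}, {0: 0.0, 1: 0.0}, {0: 1.0, 1: 1.0},
                                 {1: {0: 1.0}})
        ll = component_loglik(ds, Dag(2, [(0, 1)]), params)
        # y-term at its conditional mean + x-term two SDs out
        expected = (-0.5 * np.log(2 * np.pi)) * 2 - 0.5 * 4.0
        assert ll[0] == pytest.approx(expected)


class TestEStep:
    def _model_1bin(self, lams, tau):
        from mixnets.em import ComponentParams
        comps = [ComponentParams({0: l}, {}, {}, {}) for l in lams]
        dags = [Dag(1, discrete=[0])] * len(lams)
        return MixtureModel(len(lams), np.array(tau), dags, comps)

    def test_k1(self):
        ds = make_dataset(np.array([[1.0], [0.0]]), n_b=1)
        model = self._model_1bin([0.5], [1.0])
        mem, tau, _ = e_step(ds, model)
        assert np.allclose(mem.gamma, 1.0) and tau[0] == 1.0

    def test_identical_components_symmetric(self):
        ds = make_dataset(np.array([[1.0], [0.0]]), n_b=1)
        model = self._model_1bin([0.3, 0.3], [0.5, 0.5])
        mem, _, _ = e_step(ds, model)
        assert np.allclose(mem.gamma, 0.5)

    def test_bayes_rule_arithmetic(self):
        ds = make_dataset(np.array([[1.0]]), n_b=1)
        model = self._model_1bin([0.9, 0.1], [0.5, 0.5])
        mem, _, _ = e_step(ds, model)
        assert np.allclose(mem.gamma[0], [0.9, 0.1])

    def test_rows_sum_to_one(self, rng):
        ds = make_dataset((rng.random((30, 1)) < 0.4).astype(float), n_b=1)
        model = self._model_1bin([0.2, 0.7, 0.5], [0.2, 0.3, 0.5])
        mem, tau, _ = e_step(ds, model)
        assert np.allclose(mem.gamma.sum(axis=1), 1.0, atol=1e-9)
        assert tau.sum() == pytest.approx(1.0)


class TestMonotonicity:
    def _setup(self, seed=0):
        cfg = SimulationConfig(K=2, n_c=8, n_b=2, cluster_sizes=(40, 40),
                               preset="medium", seed=seed)
        return generate_mixture(cfg)

    def test_mle_observed_loglik_non_decreasing(self):
        # at fixed structures, exact weighted-ML M-steps can only improve
        # the observed-data likelihood
        b = self._setup()
        ds = b.dataset
        mem = init_memberships(ds, 2, 0)
        gamma, tau = mem.gamma, mem.gamma.mean(axis=0)
        model = MixtureModel(2, tau, b.truth.dags, [None, None])
        lls = []
        for _ in range(25):
            model.params = [m_step_params(ds, gamma[:, k], model.dags[k],
                                          estimator="mle") for k in range(2)]
            model.tau = tau
            mem, tau, ll = e_step(ds, model)
            gamma = mem.gamma
            lls.append(ll)
        assert np.diff(lls).min() >= -1e-6

    def test_map_penalized_objective_non_decreasing(self):
        # the default M-step maximizes surrogate + log prior, so the
        # penalized observed objective ascends
        b = self._setup(1)
        ds = b.dataset
        n = ds.n_features
        mem = init_memberships(ds, 2, 0)
        gamma, tau = mem.gamma, mem.gamma.mean(axis=0)
        model = MixtureModel(2, tau, b.truth.dags, [None, None])
        objs = []
        for _ in range(25):
            model.params = [m_step_params(ds, gamma[:, k], model.dags[k])
                            for k in range(2)]
            model.tau = tau
            mem, tau, ll = e_step(ds, model)
            gamma = mem.gamma
            objs.append(ll + sum(log_parameter_prior(p, n)
                                 for p in model.params))
        assert np.diff(objs).min() >= -1e-6


class TestFit:
    def test_k1_equals_single_component(self, rng):
        cfg = SimulationConfig(K=1, n_c=6, n_b=2, cluster_sizes=(60,),
                               eta=0.0, delta=0.0, seed=0)
        b = generate_mixture(cfg)
        res = fit(b.dataset, 1, FitConfig(), seed=0)
        assert np.allclose(res.memberships.gamma, 1.0)
        per_sample = component_loglik(b.dataset, res.model.dags[0],
                                      res.model.params[0])
        assert res.model.loglik == pytest.approx(per_sample.sum(), rel=1e-9)

    def test_trivially_separable_mixture(self):
        cfg = SimulationConfig(K=2, n_c=10, n_b=0, cluster_sizes=(100, 100),
                               eta=0.0, delta=1.0, shift=3.0, seed=3)
        b = generate_mixture(cfg)
        res = fit(b.dataset, 2, FitConfig(), seed=5)
        assert ari(res.memberships.hard, b.labels) == 1.0

    def test_determinism(self):
        cfg = SimulationConfig(K=2, n_c=6, n_b=2, cluster_sizes=(30, 30),
                               preset="medium", seed=0)
        b = generate_mixture(cfg)
        r1 = fit(b.dataset, 2, FitConfig(max_outer=3), seed=9)
        r2 = fit(b.dataset, 2, FitConfig(max_outer=3), seed=9)
        assert np.allclose(r1.memberships.gamma, r2.memberships.gamma)
        assert r1.model.loglik == r2.model.loglik

    def test_zero_variance_column_rejected(self, rng):
        x = rng.normal(size=(20, 3))
        x[:, 1] = 7.0
        ds = make_dataset(x)
        with pytest.raises(ValueError, match="zero-variance"):
            fit(ds, 1, FitConfig(), seed=0)


class TestInformationCriteria:
    def _model(self, K, dags, loglik):
        m = MixtureModel(K, np.ones(K) / K, dags, [None] * K)
        m.loglik = loglik
        return m

    def test_parameter_count_rule(self):
        model = self._model(1, [Dag(2, discrete=[0])], -10.0)
        aic, bic = information_criteria(model, N=20, n_b=1, n_o=0, n_c=1)
        d = 3  # 1 Bernoulli + 2 Gaussian, no edges, K-1 = 0
        assert aic == pytest.approx(-2 * -10.0 + 2 * d)
        assert bic == pytest.approx(-2 * -10.0 + d * np.log(20))

    def test_edge_adds_one_parameter(self):
        base = self._model(2, [Dag(3, discrete=[0])] * 2, -5.0)
        plus = self._model(2, [Dag(3, [(0, 1)], discrete=[0]),
                               Dag(3, discrete=[0])], -5.0)
        aic0, _ = information_criteria(base, 10, 1, 0, 2)
        aic1, _ = information_criteria(plus, 10, 1, 0, 2)
        assert aic1 - aic0 == pytest.approx(2.0)

    def test_bic_exceeds_aic_for_large_n(self):
        model = self._model(1, [Dag(2, discrete=[0])], -10.0)
        aic, bic = information_criteria(model, N=8, n_b=1, n_o=0, n_c=1)
        assert bic > aic  # log 8 > 2

    def test_label_permutation_invariance(self):
        dags = [Dag(3, [(0, 1)], discrete=[0]), Dag(3, discrete=[0])]
        m1 = self._model(2, dags, -7.0)
        m2 = self._model(2, dags[::-1], -7.0)
        assert information_criteria(m1, 15, 1, 0, 2) == \
            information_criteria(m2, 15, 1, 0, 2)


class TestSelectK:
    def test_table_shape_and_k1_truth(self):
        cfg = SimulationConfig(K=1, n_c=5, n_b=2, cluster_sizes=(120,),
                               eta=0.0, delta=0.0, seed=2)
        b = generate_mixture(cfg)
        table, chosen, _ = select_k(b.dataset, 1, 3, "bic",
                                    FitConfig(max_outer=5), seed=0)
        assert len(table) == 3
        assert chosen == 1

    def test_bad_inputs(self, rng):
        ds = make_dataset(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError):
            select_k(ds, 2, 1, "bic")
        with pytest.raises(ValueError):
            select_k(ds, 1, 2, "waic")
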