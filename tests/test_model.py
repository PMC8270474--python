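import numpy as np
import pytest
from scipy import stats

import diseasemap as dm
from diseasemap.model import (ModelInputError, ConfigError, PriorSpec, SamplerOptions,
                              precision_posterior)

from _oracles import pairwise_quadratic_bruteforce, spacetime_alpha_posterior_mean
from conftest import random_graph


class TestICARConditional:
    def test_two_neighbor_example(self, path_graph):
        # site B has neighbors A and C
        mean, var = dm.icar_conditional([1.0, 0.0, 3.0, 0.0], path_graph, 1, sigma2_eta=2.0)
        assert mean == pytest.approx(2.0)
        assert var == pytest.approx(1.0)

    def test_single_neighbor_returns_its_value(self, path_graph):
        mean, var = dm.icar_conditional([0.0, 1.7, 0.0, 0.0], path_graph, 0, sigma2_eta=0.5)
        assert mean == pytest.approx(1.7)
        assert var == pytest.approx(0.5)

    def test_zero_neighbors_give_zero_mean(self, path_graph):
        mean, _ = dm.icar_conditional([0.0, 0.0, 5.0, 0.0], path_graph, 1, sigma2_eta=1.0)
        assert mean == pytest.approx(2.5)  # neighbors A=0, C=5

    def test_island_raises(self):
        g = dm.build_adjacency([("A", "B")], ["A", "B", "C"])
        with pytest.raises(ModelInputError, match="no neighbors"):
            dm.icar_conditional([0.0, 0.0, 0.0], g, 2, 1.0)


class TestQuadraticForms:
    def test_constant_field_is_zero(self, lattice_4x5):
        assert dm.icar_quadratic_form(np.full(20, 3.3), lattice_4x5) == 0.0

    def test_single_edge_difference(self):
        g = dm.build_adjacency([("A", "B")], ["A", "B"])
        assert dm.icar_quadratic_form([0.0, 2.0], g) == pytest.approx(4.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            g = random_graph(rng, n_max=50)
            eta = rng.normal(size=g.n_regions)
            assert dm.icar_quadratic_form(eta, g) == pytest.approx(
                pairwise_quadratic_bruteforce(eta, g), abs=1e-12)

    def test_rw1_form(self):
        assert dm.rw1_quadratic_form([0.0, 1.0, 3.0]) == pytest.approx(1.0 + 4.0)


class TestRW1Conditional:
    def test_interior_averages_neighbors(self):
        mean, var = dm.rw1_conditional([0.0, 9.0, 4.0], 1, sigma2_phi=2.0)
        assert mean == pytest.approx(2.0)
        assert var == pytest.approx(1.0)

    def test_first_period_follows_second(self):
        mean, var = dm.rw1_conditional([0.0, 1.4, 9.0], 0, sigma2_phi=0.7)
        assert mean == pytest.approx(1.4)
        assert var == pytest.approx(0.7)

    def test_last_period_follows_previous(self):
        mean, var = dm.rw1_conditional([0.0, 1.4, 9.0], 2, sigma2_phi=0.7)
        assert mean == pytest.approx(1.4)
        assert var == pytest.approx(0.7)

    def test_single_period_invalid(self):
        with pytest.raises(ModelInputError):
            dm.rw1_conditional([1.0], 0, 1.0)


class TestPrecisionUpdate:
    def test_iid_zero_effects_posterior_moments(self):
        prior = PriorSpec()
        n = 30
        shape, rate = precision_posterior(np.zeros(n), "iid", prior)
        assert shape == pytest.approx(0.1 + n / 2)
        assert rate == pytest.approx(0.01)
        rng = np.random.default_rng(0)
        draws = np.array([dm.update_precision(np.zeros(n), "iid", prior, rng)
                          for _ in range(20_000)])
        assert np.mean(draws) == pytest.approx(shape / rate, rel=0.02)

    def test_icar_rank_deducts_components(self, lattice_10x10):
        prior = PriorSpec()
        # connected 10-region path: rank 9
        g = dm.make_lattice(1, 10)
        eta = np.zeros(10)
        shape, _ = precision_posterior(eta, "icar", prior, graph=g)
        assert shape == pytest.approx(0.1 + 9 / 2)
        # two components + one island: rank n - c = 5 - 3
        g2 = dm.build_adjacency([("A", "B"), ("C", "D")], ["A", "B", "C", "D", "E"])
        shape2, _ = precision_posterior(np.zeros(5), "icar", prior, graph=g2)
        assert shape2 == pytest.approx(0.1 + 1.0)

    def test_rw1_constant_reduces_to_prior_rate(self):
        prior = PriorSpec()
        shape, rate = precision_posterior(np.full(6, 2.2), "rw1", prior)
        assert shape == pytest.approx(0.1 + 5 / 2)
        assert rate == pytest.approx(0.01)

    def test_bad_structure_rejected(self):
        with pytest.raises(ConfigError):
            precision_posterior(np.zeros(3), "ar2", PriorSpec())


class TestGelmanRubin:
    def test_iid_normal_chains_near_one(self):
        rng = np.random.default_rng(8)
        chains = rng.normal(size=(2, 5000))
        assert dm.gelman_rubin(chains) < 1.01

    def test_separated_chains_far_above_threshold(self):
        rng = np.random.default_rng(8)
        chains = np.vstack([rng.normal(0, 1, 2000), rng.normal(10, 1, 2000)])
        assert dm.gelman_rubin(chains) > 3.0

    def test_identical_constant_chains_return_one(self):
        chains = np.ones((3, 100))
        assert dm.gelman_rubin(chains) == pytest.approx(1.0, abs=1e-6)

    def test_single_chain_rejected(self):
        with pytest.raises(ModelInputError):
            dm.gelman_rubin(np.zeros((1, 100)))


@pytest.fixture(scope="module")
def null_fit(lattice_4x5):
    """Y = E exactly on a 4x5 lattice: the SIR is identically 1."""
    n = 20
    table = dm.CountTable(lattice_4x5.region_ids, np.full(n, 5), E=np.full(n, 5.0))
    model = dm.SpatialCountModel(table, lattice_4x5)
    return model.fit(n_chains=2, n_iterations=4000, n_burnin=1000, thin=2, seed=3)


class TestSpatialFit:
    def test_alpha_concentrates_near_zero_when_y_equals_e(self, null_fit):
        a = null_fit.draws.pooled("alpha")
        assert abs(np.mean(a)) < 2 * np.std(a)

    def test_eta_draws_sum_to_zero(self, null_fit):
        eta = null_fit.draws.pooled("eta")
        assert np.max(np.abs(eta.sum(axis=1))) < 1e-9

    def test_acceptance_rates_in_unit_interval(self, null_fit):
        for name, rate in null_fit.draws.acceptance.items():
            assert 0.0 <= rate <= 1.0, name

    def test_retained_draw_count_matches_budget(self, null_fit):
        opt = null_fit.draws.options
        assert null_fit.draws.n_draws == (opt.n_iterations - opt.n_burnin) // opt.thin

    def test_beta_recovery_within_three_posterior_sd(self):
        # 10x10 lattice with a single covariate at IRR ~ 0.9
        rng = np.random.default_rng(44)
        g = dm.make_lattice(10, 10)
        x = rng.normal(size=100)
        beta_true = -0.105
        u = rng.normal(0, 0.1, size=100)
        eta = dm.simulate_structured_field(g, 0.1, seed=9)
        E = np.full(100, 40.0)
        Y = rng.poisson(E * np.exp(0.2 + beta_true * x + u + eta))
        table = dm.CountTable(g.region_ids, Y, E=E)
        model = dm.SpatialCountModel(table, g, covariates=x[:, None],
                                     covariate_names=("x0",))
        res = model.fit(n_chains=2, n_iterations=4000, n_burnin=1500, thin=2, seed=5)
        b = res.draws.pooled("beta:x0")
        assert abs(np.mean(b) - beta_true) < 3 * np.std(b)

    def test_misaligned_regions_rejected(self, lattice_4x5):
        table = dm.CountTable(tuple(reversed(lattice_4x5.region_ids)),
                              np.ones(20, dtype=int), E=np.ones(20))
        with pytest.raises(ModelInputError, match="same order"):
            dm.SpatialCountModel(table, lattice_4x5)

    def test_zero_expected_count_rejected(self, lattice_4x5):
        E = np.ones(20)
        E[3] = 0.0
        table = dm.CountTable(lattice_4x5.region_ids, np.ones(20, dtype=int), E=E)
        with pytest.raises(ModelInputError, match="positive expected"):
            dm.SpatialCountModel(table, lattice_4x5)

    def test_all_zero_counts_rejected(self, lattice_4x5):
        table = dm.CountTable(lattice_4x5.region_ids, np.zeros(20, dtype=int),
                              E=np.ones(20))
        with pytest.raises(ModelInputError, match="improper"):
            dm.SpatialCountModel(table, lattice_4x5).fit(
                n_chains=2, n_iterations=200, n_burnin=100)


class TestSpatioTemporalFit:
    def test_single_period_directed_to_spatial_model(self, lattice_4x5):
        table = dm.CountTable(lattice_4x5.region_ids, np.ones((20, 1), dtype=int),
                              E=np.ones((20, 1)))
        with pytest.raises(ModelInputError, match="T >= 2"):
            dm.SpatioTemporalCountModel(table, lattice_4x5)

    def test_phi_draws_sum_to_zero_and_match_quadrature(self):
        g = dm.build_adjacency([("A", "B")], ["A", "B"])
        Y = np.array([[2, 3], [4, 1]])
        E = np.full((2, 2), 1.5)
        table = dm.CountTable(("A", "B"), Y, E=E, periods=("p1", "p2"))
        model = dm.SpatioTemporalCountModel(table, g)
        res = model.fit(n_chains=2, n_iterations=30_000, n_burnin=5_000, thin=5, seed=11,
                        fixed_precisions={"tau_u": 1.0, "tau_eta": 1.0,
                                          "tau_gamma": 1e8, "tau_phi": 1.0})
        phi = res.draws.pooled("phi")
        assert np.max(np.abs(phi.sum(axis=1))) < 1e-9
        oracle = spacetime_alpha_posterior_mean(Y, E, sigma2_u=1.0, sigma2_phi=1.0)
        assert abs(res.posterior_mean("alpha") - oracle) < 0.05

    def test_nests_spatial_model_when_temporal_variance_pinned(self, small_registry):
        reg = small_registry
        ids = reg.graph.region_ids
        scheme = ((1992, 1996), (1997, 2001), (2002, 2006))
        pt = dm.expected_counts_by_period(reg.cases, reg.populations, ids, scheme)
        flat = dm.expected_counts(reg.cases, reg.populations, ids)
        stm = dm.SpatioTemporalCountModel(pt, reg.graph, covariates=reg.covariates,
                                          covariate_names=("sesi",))
        sp = dm.SpatialCountModel(flat, reg.graph, covariates=reg.covariates,
                                  covariate_names=("sesi",))
        # pin the temporal effects at ~0: the spatio-temporal fit collapses
        # onto the spatial one
        r1 = stm.fit(n_chains=2, n_iterations=4000, n_burnin=1500, thin=2, seed=2,
                     fixed_precisions={"tau_gamma": 1e8, "tau_phi": 1e8})
        r2 = sp.fit(n_chains=2, n_iterations=4000, n_burnin=1500, thin=2, seed=2)
        b1 = r1.draws.pooled("beta:sesi")
        b2 = r2.draws.pooled("beta:sesi")
        se = np.sqrt(np.var(b1) / 200 + np.var(b2) / 200)  # generous MC error
        assert abs(np.mean(b1) - np.mean(b2)) < 4 * se


class TestOptionsValidation:
    def test_burnin_must_be_less_than_iterations(self):
        with pytest.raises(ConfigError):
            SamplerOptions(n_iterations=100, n_burnin=100)

    def test_thin_must_be_positive(self):
        with pytest.raises(ConfigError):
            SamplerOptions(thin=0)

    def test_bad_prior_parameters(self):
        with pytest.raises(ConfigError):
            PriorSpec(precision_shape=0.0)

    def test_unknown_fixed_precision_rejected(self, lattice_4x5):
        table = dm.CountTable(lattice_4x5.region_ids, np.ones(20, dtype=int),
                              E=np.ones(20))
        with pytest.raises(ConfigError, match="tau_zeta"):
            dm.SpatialCountModel(table, lattice_4x5).fit(
                n_chains=1, n_iterations=200, n_burnin=100,
                fixed_precisions={"tau_zeta": 1.0})
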