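"""Variational model: likelihood primitives, ELBO terms, training, inference."""

import numpy as np
import pytest
from scipy import stats

from spotdecon import model as M
from spotdecon._autodiff import Tensor, softmax
from spotdecon.model import (GenerativeConfig, decode_mean_expression,
                             expression_elbo, infer, joint_elbo, nb_log_pmf,
                             poe_combine, predict_state_expression, train)
from spotdecon.priors import build_priors


class TestDecoder:
    def test_output_sums_to_one(self):
        rng = np.random.default_rng(0)
        W, b = rng.standard_normal((4, 20)), rng.standard_normal(20)
        out = decode_mean_expression(rng.standard_normal(4), (W, b))
        assert abs(out.sum() - 1) < 1e-6 and np.all(out >= 0)

    def test_zero_weights_give_uniform(self):
        out = decode_mean_expression(np.zeros(3), (np.zeros((3, 10)),
                                                   np.zeros(10)))
        np.testing.assert_allclose(out, 0.1)

    def test_matches_direct_softmax_computation(self):
        rng = np.random.default_rng(1)
        W, b = rng.standard_normal((5, 12)), rng.standard_normal(12)
        z = rng.standard_normal(5)
        logits = z @ W + b
        ref = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(decode_mean_expression(z, (W, b)), ref,
                                   rtol=1e-12)

    def test_non_finite_latent_rejected(self):
        with pytest.raises(ValueError):
            decode_mean_expression(np.array([np.nan]), (np.zeros((1, 2)),
                                                        np.zeros(2)))


class TestNegativeBinomial:
    def test_pmf_normalizes_over_truncated_support(self):
        x = np.arange(0, 10001)
        total = np.exp(nb_log_pmf(x, 5.0, 2.0)).sum()
        assert abs(total - 1.0) < 1e-6

    def test_poisson_limit_at_large_theta(self):
        x = np.arange(0, 30)
        nb = nb_log_pmf(x, 1.0, 1e8)
        pois = stats.poisson.logpmf(x, 1.0)
        np.testing.assert_allclose(nb, pois, atol=1e-4)

    def test_closed_form_at_zero(self):
        mu, theta = 3.7, 1.9
        np.testing.assert_allclose(nb_log_pmf(0, mu, theta),
                                   theta * np.log(theta / (theta + mu)),
                                   rtol=1e-12)

    def test_mean_variance_relation(self):
        # empirical check through scipy's NB parameterization
        mu, theta = 8.0, 3.0
        n, p = theta, theta / (theta + mu)
        ref = stats.nbinom.logpmf(np.arange(50), n, p)
        np.testing.assert_allclose(nb_log_pmf(np.arange(50), mu, theta), ref,
                                   rtol=1e-10)

    def test_invalid_domain_rejected(self):
        with pytest.raises(ValueError):
            nb_log_pmf(-1, 1.0, 1.0)


class TestPoE:
    def test_equal_precision_average(self):
        mu, var = poe_combine(0.0, 1.0, 2.0, 1.0)
        assert mu == 1.0 and var == 0.5

    def test_uninformative_expert_vanishes(self):
        mu, var = poe_combine(0.3, 0.7, 99.0, 1e12)
        np.testing.assert_allclose([mu, var], [0.3, 0.7], rtol=1e-6)

    def test_matches_renormalized_density_product_on_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            m1, m2 = rng.normal(size=2)
            v1, v2 = rng.uniform(0.2, 2.0, size=2)
            grid = np.linspace(-10, 10, 20001)
            prod = stats.norm.pdf(grid, m1, np.sqrt(v1)) * \
                stats.norm.pdf(grid, m2, np.sqrt(v2))
            prod /= np.trapezoid(prod, grid)
            mean_num = np.trapezoid(grid * prod, grid)
            var_num = np.trapezoid((grid - mean_num) ** 2 * prod, grid)
            mu, var = poe_combine(m1, v1, m2, v2)
            np.testing.assert_allclose([mu, var], [mean_num, var_num],
                                       atol=1e-6)

    def test_commutative_and_associative(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=3)
        v = rng.uniform(0.1, 3.0, size=3)
        a = poe_combine(m[0], v[0], m[1], v[1])
        b = poe_combine(m[1], v[1], m[0], v[0])
        np.testing.assert_allclose(a, b, atol=1e-12)
        left = poe_combine(*poe_combine(m[0], v[0], m[1], v[1]), m[2], v[2])
        right = poe_combine(m[0], v[0], *poe_combine(m[1], v[1], m[2], v[2]))
        np.testing.assert_allclose(left, right, atol=1e-10)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            poe_combine(0.0, 0.0, 1.0, 1.0)


class TestKLTerms:
    def test_dirichlet_kl_zero_when_posterior_equals_prior(self):
        rng = np.random.default_rng(0)
        A = rng.dirichlet(np.ones(4), size=6)
        kl = M._kl_dirichlet(Tensor(50.0 * A), 50.0 * A)
        np.testing.assert_allclose(kl.data, 0.0, atol=1e-10)

    def test_gaussian_kl_zero_at_equality_and_closed_form(self):
        m = Tensor(np.array([[1.0, -2.0]]))
        v = Tensor(np.array([[0.5, 2.0]]))
        np.testing.assert_allclose(M._kl_normal(m, v, m, v).data, 0.0,
                                   atol=1e-12)
        # KL(N(m, v) || N(0, 10)) against the closed form, independently
        kl = M._kl_normal(m, v, 0.0, 10.0).data
        ref = 0.5 * (np.log(10.0 / v.data) + (v.data + m.data ** 2) / 10.0
                     - 1.0)
        np.testing.assert_allclose(kl, ref, rtol=1e-12)

    def test_dirichlet_kl_matches_monte_carlo(self):
        rng = np.random.default_rng(2)
        a = np.array([[3.0, 1.5, 2.2]])
        b = np.array([[1.0, 4.0, 2.0]])
        kl = M._kl_dirichlet(Tensor(a), b).data[0]
        draws = rng.dirichlet(a[0], size=400000)
        mc = np.mean(stats.dirichlet.logpdf(draws.T, a[0])
                     - stats.dirichlet.logpdf(draws.T, b[0]))
        np.testing.assert_allclose(kl, mc, rtol=0.02)


@pytest.fixture(scope="module")
def trained(small_sim_module):
    sim, priors = small_sim_module
    cfg = GenerativeConfig(epochs=40, restarts=1, seed=0, hidden=64)
    state = train(sim.data, priors, None, cfg)
    return sim, priors, state


@pytest.fixture(scope="module")
def small_sim_module():
    from spotdecon import priors as P
    from spotdecon import simulate
    sim = simulate.simulate_dataset("major", grid_side=7, seed=1)
    return sim, P.build_priors(sim.data, sim.signatures(), seed=0)


class TestTraining:
    def test_single_state_proportions_are_exactly_one(self, small_sim_module):
        from spotdecon.core_io import SignatureSet
        sim, _ = small_sim_module
        sigs = SignatureSet(["only"],
                            {"only": sim.reference.marker_blocks["type0"]})
        priors = build_priors(sim.data, sigs, seed=0)
        cfg = GenerativeConfig(epochs=5, restarts=1, seed=0, hidden=32)
        state = train(sim.data, priors, None, cfg)
        res = infer(sim.data, None, state)
        np.testing.assert_array_equal(res.c, 1.0)

    def test_elbo_improves_over_training(self, trained):
        _, _, state = trained
        assert state.elbo_trace[-1] > state.elbo_trace[0]

    def test_same_seed_reproduces_proportions_bitwise(self, small_sim_module):
        sim, priors = small_sim_module
        cfg = dict(epochs=8, restarts=1, seed=5, hidden=32)
        r1 = infer(sim.data, None,
                   train(sim.data, priors, None, GenerativeConfig(**cfg)))
        r2 = infer(sim.data, None,
                   train(sim.data, priors, None, GenerativeConfig(**cfg)))
        assert np.max(np.abs(r1.c - r2.c)) < 1e-10

    def test_patches_ignored_without_poe_flag(self, small_sim_module):
        from spotdecon.core_io import extract_patches
        from spotdecon.simulate import render_pseudo_histology
        sim, priors = small_sim_module
        img = render_pseudo_histology(sim, seed=0)
        patches = extract_patches(sim.data, img, P=10)
        cfg = dict(epochs=6, restarts=1, seed=2, hidden=32)
        a = train(sim.data, priors, None,
                  GenerativeConfig(poe_enabled=False, **cfg))
        b = train(sim.data, priors, patches,
                  GenerativeConfig(poe_enabled=False, **cfg))
        for k in a.params:
            np.testing.assert_array_equal(a.params[k].data, b.params[k].data)

    def test_poe_requires_patches(self, small_sim_module):
        sim, priors = small_sim_module
        with pytest.raises(ValueError, match="patches"):
            train(sim.data, priors, None,
                  GenerativeConfig(poe_enabled=True, epochs=2, restarts=1))

    def test_kl_terms_nonnegative_during_training(self, small_sim_module):
        sim, priors = small_sim_module
        cfg = GenerativeConfig(epochs=4, restarts=1, seed=0, hidden=32)
        cfg.K = priors.A.shape[1]
        rng = np.random.default_rng(0)
        p = M._init_params(sim.data.n_genes, cfg.K, cfg, rng)
        _, terms = expression_elbo(sim.data.counts, priors.A,
                                   np.log(priors.lib_prior), p, cfg, rng)
        for name in ("kl_z", "kl_c", "kl_l", "kl_u"):
            assert terms[name].item() >= -1e-8


@pytest.fixture(scope="module")
def poe_setup(small_sim_module):
    from spotdecon.core_io import extract_patches
    from spotdecon.simulate import render_pseudo_histology
    sim, priors = small_sim_module
    img = render_pseudo_histology(sim, seed=0)
    patches = extract_patches(sim.data, img, P=8)
    return sim, priors, patches


class TestJointObjective:
    def test_zero_ib_weight_reduces_to_joint_term(self, poe_setup):
        sim, priors, patches = poe_setup
        cfg = GenerativeConfig(poe_enabled=True, ib_weight=0.0, hidden=32)
        cfg.K = priors.A.shape[1]
        p = M._init_params(sim.data.n_genes, cfg.K, cfg,
                           np.random.default_rng(0),
                           patch_dim=patches.flattened().shape[1])
        _, terms = joint_elbo(sim.data.counts, patches.flattened(), priors.A,
                              np.log(priors.lib_prior), p, cfg,
                              np.random.default_rng(1))
        np.testing.assert_allclose(terms["elbo"].item(),
                                   terms["joint"].item(), rtol=1e-12)

    def test_total_decomposes_into_weighted_views(self, poe_setup):
        sim, priors, patches = poe_setup
        a = 5.0
        cfg = GenerativeConfig(poe_enabled=True, ib_weight=a, hidden=32)
        cfg.K = priors.A.shape[1]
        p = M._init_params(sim.data.n_genes, cfg.K, cfg,
                           np.random.default_rng(0),
                           patch_dim=patches.flattened().shape[1])
        _, terms = joint_elbo(sim.data.counts, patches.flattened(), priors.A,
                              np.log(priors.lib_prior), p, cfg,
                              np.random.default_rng(1))
        recomposed = terms["joint"].item() + a * (
            terms["expression_elbo"].item() + terms["histology_elbo"].item())
        np.testing.assert_allclose(terms["elbo"].item(), recomposed,
                                   atol=1e-10)

    def test_poe_training_runs_and_reconstructs_images(self, poe_setup):
        sim, priors, patches = poe_setup
        cfg = GenerativeConfig(poe_enabled=True, epochs=6, restarts=1,
                               seed=0, hidden=32)
        state = train(sim.data, priors, patches, cfg)
        res = infer(sim.data, patches, state)
        assert res.recon_img is not None
        assert res.recon_img.shape == patches.flattened().shape
        assert np.all(np.isfinite(res.recon_img))


class TestInference:
    def test_proportion_rows_sum_to_one(self, trained):
        sim, _, state = trained
        res = infer(sim.data, None, state)
        np.testing.assert_allclose(res.c.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(res.c >= 0) and np.all(res.l > 0)

    def test_inference_is_deterministic(self, trained):
        sim, _, state = trained
        a = infer(sim.data, None, state)
        b = infer(sim.data, None, state)
        np.testing.assert_array_equal(a.c, b.c)
        np.testing.assert_array_equal(a.z, b.z)

    def test_untrained_state_rejected(self, trained):
        sim, priors, state = trained
        from spotdecon.model import VariationalState
        blank = VariationalState(params=state.params, cfg=state.cfg,
                                 priors=priors, trained=False)
        with pytest.raises(ValueError):
            infer(sim.data, None, blank)

    def test_state_profile_sums_to_one_and_tracks_reference(self, trained):
        sim, _, state = trained
        K = sim.truth_proportions.shape[1]
        ref_means = sim.reference.type_means
        ref_norm = ref_means / ref_means.sum(axis=1, keepdims=True)
        better = 0
        for k in range(K):
            prof = predict_state_expression(state, k, sim.data)
            np.testing.assert_allclose(prof.sum(), 1.0, atol=1e-6)
            corrs = [np.corrcoef(prof, ref_norm[j])[0, 1] for j in range(K)]
            if np.argmax(corrs) == k:
                better += 1
        assert better >= K - 1  # at most one state confused on tiny data

    def test_invalid_state_index_rejected(self, trained):
        sim, _, state = trained
        with pytest.raises(ValueError):
            predict_state_expression(state, 99, sim.data)
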