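"""Two-level mixture density, E/M-step and EM fitting, checked against
brute-force enumeration over latent configurations."""

import itertools

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from discoset import (
    MixtureParams,
    cc_density,
    ci_density,
    e_step,
    fit_em,
    loglik,
    m_step,
    two_level_density,
)
from discoset.mixture import auto_init

from conftest import random_params


# ---------------------------------------------------------------------------
# independent oracles

def phi(z, mu, s2):
    return norm.pdf(z, loc=mu, scale=np.sqrt(s2))


def ci_brute(z_row, p):
    """f_CI by summing all 3**K state lists."""
    total = 0.0
    for lst in itertools.product(range(3), repeat=p.K):
        term = 1.0
        for k, j in enumerate(lst):
            term *= p.rho[j, k] * phi(z_row[k], p.mu[j, k], p.sigma2[j, k])
        total += term
    return total


def cc_brute(z_row, p):
    return sum(p.pi[j] * np.prod([phi(z_row[k], p.mu[j, k], p.sigma2[j, k])
                                  for k in range(p.K)])
               for j in range(3))


def posterior_brute(z_row, p):
    """Posterior over every latent configuration: 3 CC states plus the
    3**K CI state lists, by direct Bayes' rule."""
    configs, weights = [], []
    for j in range(3):
        dens = np.prod([phi(z_row[k], p.mu[j, k], p.sigma2[j, k])
                        for k in range(p.K)])
        configs.append(("CC", j))
        weights.append(p.lam * p.pi[j] * dens)
    for lst in itertools.product(range(3), repeat=p.K):
        dens = np.prod([p.rho[j, k] * phi(z_row[k], p.mu[j, k], p.sigma2[j, k])
                        for k, j in enumerate(lst)])
        configs.append(("CI", lst))
        weights.append((1 - p.lam) * dens)
    weights = np.array(weights) / np.sum(weights)
    return configs, weights


# ---------------------------------------------------------------------------
# densities

def test_ci_density_is_one_dim_mixture_at_k1():
    p = MixtureParams(0.3, np.array([1/3, 1/3, 1/3]),
                      np.array([[0.5], [0.3], [0.2]]),
                      np.array([[0.0], [2.0], [-2.0]]),
                      np.array([[1.0], [1.5], [0.8]]))
    z = 1.3
    expected = sum(p.rho[j, 0] * phi(z, p.mu[j, 0], p.sigma2[j, 0])
                   for j in range(3))
    assert ci_density(np.array([z]), p) == pytest.approx(expected, rel=1e-12)


def test_ci_density_pure_null_reduces_to_product_of_standard_normals(rng):
    K = 4
    p = random_params(rng, K)
    p.rho = np.tile(np.array([1.0, 0.0, 0.0])[:, None], (1, K))
    z = rng.normal(size=K)
    assert ci_density(z, p) == pytest.approx(np.prod(norm.pdf(z)), rel=1e-12)


def test_ci_density_matches_brute_force_enumeration(rng):
    p = random_params(rng, 3)
    z = np.array([1.0, -0.5, 2.0])
    assert ci_density(z, p) == pytest.approx(ci_brute(z, p), rel=1e-10)


def test_cc_density_pure_null_and_hand_sum(rng):
    p = random_params(rng, 2)
    z = np.array([0.7, -1.1])
    assert cc_density(z, p) == pytest.approx(cc_brute(z, p), rel=1e-12)
    p.pi = np.array([1.0, 0.0, 0.0])
    assert cc_density(z, p) == pytest.approx(np.prod(norm.pdf(z)), rel=1e-12)


def test_models_coincide_at_k1_when_pi_equals_rho(rng):
    p = random_params(rng, 1)
    p.pi = p.rho[:, 0].copy()
    z = np.array([0.4])
    assert cc_density(z, p) == pytest.approx(ci_density(z, p), rel=1e-12)


def test_two_level_density_boundaries_and_normalisation(rng):
    p = random_params(rng, 2)
    z = rng.normal(size=2)
    p.lam = 0.0
    assert two_level_density(z, p) == pytest.approx(ci_density(z, p), rel=1e-12)
    p.lam = 1.0
    assert two_level_density(z, p) == pytest.approx(cc_density(z, p), rel=1e-12)

    p1 = random_params(rng, 1)
    integral, _ = quad(lambda z: two_level_density(np.array([z]), p1),
                       -30, 30, limit=200)
    assert integral == pytest.approx(1.0, abs=1e-6)


def test_loglik_closed_form_and_additivity(rng):
    K = 3
    p = random_params(rng, K)
    p.lam, p.pi = 1.0, np.array([1.0, 0.0, 0.0])
    z0 = np.zeros((1, K))
    assert loglik(z0, p) == pytest.approx(K * norm.logpdf(0.0), rel=1e-12)

    p = random_params(rng, 2)
    a, b = rng.normal(size=(5, 2)), rng.normal(size=(3, 2))
    assert loglik(np.vstack([a, b]), p) == pytest.approx(
        loglik(a, p) + loglik(b, p), rel=1e-12)
    # direct density summation on a small instance
    direct = sum(np.log(two_level_density(row, p)) for row in a)
    assert loglik(a, p) == pytest.approx(direct, rel=1e-10)


# ---------------------------------------------------------------------------
# E-step

def test_e_step_boundaries(rng):
    p = random_params(rng, 2)
    z = rng.normal(size=(4, 2))
    p.lam = 0.0
    post = e_step(z, p)
    assert np.allclose(post.omega, 0.0)
    p.lam = 1.0
    post = e_step(z, p)
    assert np.allclose(post.omega, 1.0)
    assert np.allclose(post.eta, 0.0)


def test_e_step_matches_bayes_enumeration(rng):
    p = random_params(rng, 2)
    z = rng.normal(size=(5, 2)) * 2
    post = e_step(z, p)
    for i in range(5):
        configs, w = posterior_brute(z[i], p)
        omega = sum(wi for c, wi in zip(configs, w) if c[0] == "CC")
        assert post.omega[i] == pytest.approx(omega, abs=1e-10)
        for j in range(3):
            xi_j = sum(wi for c, wi in zip(configs, w)
                       if c[0] == "CC" and c[1] == j)
            assert post.xi[i, j] == pytest.approx(xi_j, abs=1e-10)
            for k in range(2):
                eta_jk = sum(wi for c, wi in zip(configs, w)
                             if c[0] == "CI" and c[1][k] == j)
                assert post.eta[i, j, k] == pytest.approx(eta_jk, abs=1e-10)


def test_posterior_membership_invariants(rng):
    for _ in range(20):
        p = random_params(rng, 4)
        z = rng.normal(size=(30, 4)) * 3
        post = e_step(z, p)
        assert np.all((post.omega >= 0) & (post.omega <= 1))
        assert np.allclose(post.xi.sum(axis=1), post.omega, atol=1e-10)
        for k in range(4):
            assert np.allclose(post.eta[:, :, k].sum(axis=1),
                               1 - post.omega, atol=1e-10)


# ---------------------------------------------------------------------------
# M-step

def test_m_step_uniform_memberships_give_half_lambda(rng):
    from discoset import PosteriorMemberships
    m, K = 6, 2
    z = rng.normal(size=(m, K))
    post = PosteriorMemberships(
        omega=np.full(m, 0.5),
        xi=np.full((m, 3), 0.5 / 3),
        eta=np.full((m, 3, K), 0.5 / 3))
    p = m_step(z, post)
    assert p.lam == pytest.approx(0.5)
    assert np.allclose(p.pi, 1 / 3)
    assert np.allclose(p.rho, 1 / 3)


def test_m_step_updates_equal_weighted_moments(rng):
    from discoset import PosteriorMemberships
    m, K = 6, 2
    z = rng.normal(size=(m, K)) + 2.0
    omega = rng.uniform(0.1, 0.9, size=m)
    xi_raw = rng.dirichlet(np.ones(3), size=m) * omega[:, None]
    eta_raw = np.stack([rng.dirichlet(np.ones(3), size=m) *
                        (1 - omega)[:, None] for _ in range(K)], axis=2)
    post = PosteriorMemberships(omega=omega, xi=xi_raw, eta=eta_raw)
    p = m_step(z, post)
    assert p.lam == pytest.approx(omega.mean())
    assert np.allclose(p.pi, xi_raw.sum(0) / xi_raw.sum())
    for k in range(K):
        assert np.allclose(p.rho[:, k],
                           eta_raw[:, :, k].sum(0) / eta_raw[:, :, k].sum())
    for j, k in [(1, 0), (1, 1)]:
        w = xi_raw[:, j] + eta_raw[:, j, k]
        mu_hand = np.sum(w * z[:, k]) / w.sum()
        if mu_hand > 0.01:  # inside the sign-clamp region
            assert p.mu[j, k] == pytest.approx(mu_hand, rel=1e-10)
            s2_hand = np.sum(w * (z[:, k] - mu_hand) ** 2) / w.sum()
            assert p.sigma2[j, k] == pytest.approx(s2_hand, rel=1e-10)


def test_m_step_keeps_null_fixed_and_signs_constrained(rng):
    from discoset import PosteriorMemberships
    m, K = 50, 3
    z = rng.normal(size=(m, K)) - 5.0  # data pulling the up-mean negative
    omega = rng.uniform(size=m)
    xi = rng.dirichlet(np.ones(3), size=m) * omega[:, None]
    eta = np.stack([rng.dirichlet(np.ones(3), size=m) * (1 - omega)[:, None]
                    for _ in range(K)], axis=2)
    p = m_step(z, PosteriorMemberships(omega, xi, eta))
    assert np.allclose(p.mu[0], 0.0)
    assert np.allclose(p.sigma2[0], 1.0)
    assert np.all(p.mu[1] > 0)
    assert np.all(p.mu[2] < 0)


# ---------------------------------------------------------------------------
# EM

def test_fit_em_lambda_zero_is_a_fixed_point(rng):
    from discoset import sample_zscores, default_truth
    zm, _ = sample_zscores(default_truth(K=2), 300, seed=5)
    init = auto_init(zm.z)
    init.lam = 0.0
    report = fit_em(zm.z, init=init, max_iter=20)
    assert report.params.lam == 0.0


def test_fit_em_loglik_nondecreasing_over_random_starts(rng):
    from discoset import sample_zscores, default_truth
    zm, _ = sample_zscores(default_truth(K=3), 500, seed=11)
    for s in range(20):
        init = random_params(np.random.default_rng(1000 + s), 3)
        report = fit_em(zm.z, init=init, max_iter=60)
        diffs = np.diff(report.loglik_trace)
        assert diffs.min() > -1e-8


def test_fit_em_requires_minimum_genes():
    from discoset import DiscosetError
    with pytest.raises(DiscosetError):
        fit_em(np.zeros((10, 2)))


def test_free_parameter_count_grows_linearly():
    for K in (1, 3, 7):
        p = MixtureParams(0.5, np.array([0.8, 0.1, 0.1]),
                          np.tile(np.array([0.8, 0.1, 0.1])[:, None], (1, K)),
                          np.vstack([np.zeros(K), np.ones(K), -np.ones(K)]),
                          np.ones((3, K)))
        assert p.n_free_parameters() == 1 + 2 + 6 * K
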