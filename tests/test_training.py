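import numpy as np
import pytest
from scipy.linalg import cholesky

from mgsm.core import sample_gsm, sample_mgsm
from mgsm.fixtures import structured_params
from mgsm.training import (TrainingConfig, _theta_from_chol, e_step, gem_fit,
                           m_step_partial, renormalize_rotational,
                           total_log_likelihood, weighted_gsm_nll)


def _small_params():
    # compact mixture for fast unit tests: 2 center, 2 groups of 2
    from mgsm.core import MGSMParams

    C_c = np.array([[0.5, 0.1], [0.1, 0.4]])
    C_s = np.stack([np.eye(2) * 0.6, np.eye(2) * 0.8])
    C_cs = []
    for g in range(2):
        C = np.eye(4) * 0.7
        C[0, 2] = C[2, 0] = 0.3
        C_cs.append(C)
    return MGSMParams(C_c, C_s, np.stack(C_cs), np.array([0.5, 0.25, 0.25]))


def test_e_step_rows_sum_to_one():
    params = _small_params()
    X, _ = sample_mgsm(params, 500, seed=1)
    R = e_step(X, params)
    assert np.all(np.abs(R.sum(axis=1) - 1.0) < 1e-10)


def test_e_step_degenerate_prior():
    params = _small_params().copy(priors=np.array([1.0, 0.0, 0.0]))
    X, _ = sample_mgsm(_small_params(), 200, seed=2)
    R = e_step(X, params)
    assert np.allclose(R, np.array([1.0, 0.0, 0.0]))


def test_e_step_separates_well_separated_components():
    """Data sampled from the no-co-assignment component is recognized."""
    params = _small_params()
    # make the co-assigned components strongly coupled so they differ
    C_cs = params.C_cs.copy()
    C_cs[:, 0, 2] = C_cs[:, 2, 0] = 0.6
    params = params.copy(C_cs=C_cs)
    only0 = params.copy(priors=np.array([1.0, 0.0, 0.0]))
    X, _ = sample_mgsm(only0, 2000, seed=3)
    R = e_step(X, params)
    assert R[:, 0].mean() > 0.6


def test_weighted_gsm_gradient_matches_finite_differences():
    rng = np.random.default_rng(1)
    n = 5
    A = rng.standard_normal((n, n + 2))
    C = A @ A.T / (n + 2) + 0.1 * np.eye(n)
    X = rng.standard_normal((60, n))
    w = rng.uniform(0.1, 1.0, 60)
    theta = _theta_from_chol(cholesky(C, lower=True))
    _, grad = weighted_gsm_nll(theta, X, w, 1e-10)
    num = np.zeros_like(theta)
    for i in range(len(theta)):
        e = np.zeros_like(theta)
        e[i] = 1e-6
        num[i] = (weighted_gsm_nll(theta + e, X, w, 1e-10)[0]
                  - weighted_gsm_nll(theta - e, X, w, 1e-10)[0]) / 2e-6
    assert np.abs(num - grad).max() < 1e-5 * max(1.0, np.abs(grad).max())


def test_m_step_updates_priors_and_does_not_decrease_objective():
    params = _small_params()
    X, _ = sample_mgsm(params, 2000, seed=4)
    for seed in range(3):
        rng = np.random.default_rng(seed)
        start = params.copy(C_cs=params.C_cs * rng.uniform(0.6, 1.6))
        R = e_step(X, start)
        before = total_log_likelihood(X, start)
        new = m_step_partial(X, R, start, "C_cs[0]", cg_max_iter=10)
        assert np.allclose(new.priors, R.mean(axis=0))
        # GEM guarantee: the marginal likelihood does not decrease
        after = total_log_likelihood(X, new)
        assert after >= before - 1e-6 * abs(before)


def test_gradient_small_at_true_parameters():
    rng = np.random.default_rng(5)
    n = 4
    A = rng.standard_normal((n, n + 2))
    C = A @ A.T / (n + 2) + 0.2 * np.eye(n)
    X = sample_gsm(C, 40000, seed=6)
    w = np.ones(len(X))
    theta = _theta_from_chol(cholesky(C, lower=True))
    f0, grad = weighted_gsm_nll(theta, X, w, 1e-10)
    # gradient per sample is near zero at the truth (finite-sample noise only)
    assert np.abs(grad).max() / len(X) < 0.02


def test_gem_monotone_and_single_component_dataset():
    params = _small_params()
    only1 = params.copy(priors=np.array([0.0, 1.0, 0.0]))
    X, _ = sample_mgsm(only1, 3000, seed=7)
    cfg = TrainingConfig(n_patches=3000, max_em_cycles=8, seed=0,
                         cg_max_iter=8, renormalize=False,
                         loglik_rel_tol=1e-7)
    fitted, trace = gem_fit(X, cfg, n_center=2, n_groups=2)
    ll = np.array(trace.loglik)
    assert np.all(np.diff(ll) >= -1e-6 * np.abs(ll[:-1]))
    assert fitted.priors[1] > 0.9


def test_restarts_converge_to_similar_likelihood():
    params = _small_params()
    X, _ = sample_mgsm(params, 2000, seed=8)
    finals = []
    for seed in (0, 123):
        cfg = TrainingConfig(n_patches=2000, max_em_cycles=10, seed=seed,
                             cg_max_iter=8, renormalize=False)
        fitted, trace = gem_fit(X, cfg, n_center=2, n_groups=2)
        finals.append(trace.loglik[-1])
    assert abs(finals[0] - finals[1]) < 0.01 * abs(finals[0])


def test_renormalization_fixed_point_and_idempotence(params_true):
    # structured fixture params are rotation-consistent by construction
    once = renormalize_rotational(params_true)
    assert np.allclose(once.C_cs, params_true.C_cs, atol=1e-12)
    assert np.allclose(once.C_s, params_true.C_s, atol=1e-12)
    twice = renormalize_rotational(once)
    assert np.allclose(twice.C_cs, once.C_cs, atol=1e-12)
    assert np.allclose(twice.C_c, once.C_c, atol=1e-12)
    assert np.allclose(twice.priors, once.priors, atol=1e-15)


def test_renormalization_enforces_rotated_copies(params_true):
    rng = np.random.default_rng(9)
    # break the symmetry of one component, then renormalize
    C_cs = params_true.C_cs.copy()
    D = np.diag(rng.uniform(0.8, 1.2, C_cs.shape[1]))
    C_cs[2] = D @ C_cs[2] @ D
    broken = params_true.copy(C_cs=C_cs)
    fixed = renormalize_rotational(broken)
    from mgsm.training import _center_rotation, _surround_rotation

    def pullback(g):
        M = np.zeros((24, 24))
        M[:8, :8] = _center_rotation(8, g, 4)
        M[8:, 8:] = _surround_rotation(16, g, 8, 4)
        return M.T @ fixed.C_cs[g] @ M

    T = pullback(0)
    for g in range(1, 4):
        assert np.allclose(pullback(g), T, atol=1e-10)


def test_training_config_validation():
    with pytest.raises(ValueError):
        TrainingConfig(max_em_cycles=0)
    with pytest.raises(ValueError):
        TrainingConfig(loglik_rel_tol=-1.0)
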