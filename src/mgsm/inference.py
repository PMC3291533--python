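"""Bayesian inference in the MGSM: generalized divisive normalization.

Model responses are posterior-mean estimates of the center Gaussian
variables.  Under a component in which the n-dimensional output vector x
shares one mixer, the posterior mean of the i-th Gaussian variable is

    g_hat_i = x_i / sqrt(lam) * K_{(n-1)/2}(lam) / K_{(n-2)/2}(lam),
    lam     = sqrt(eps + x' C^{-1} x),

which is divisive normalization: ``lam`` is the normalization signal and the
Bessel ratio a slowly varying correction (it diverges at 0 and asymptotes to
1 at infinity).  The full response mixes the component-conditional estimates
weighted by the posterior probability of each co-assignment configuration, so
the normalization *pool* itself is stimulus dependent.  Even/odd phase
estimates are combined in quadrature into orientation-tuned, phase-invariant
responses.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import logsumexp

from .core import MGSMParams, bessel_ratio, component_log_densities

__all__ = [
    "InferenceResult", "lambda_term", "estimate_coassigned",
    "estimate_independent", "posterior_components", "respond",
    "respond_batch", "modulation_index",
]


@dataclass
class InferenceResult:
    posterior: np.ndarray    # (G+1,) component probabilities
    g_hat: np.ndarray        # (n_center,) expected Gaussian values
    response: np.ndarray     # (n_orientations,) phase-invariant responses
    lambdas: dict            # normalization signals: lambda_c, lambda_cs[g]


def lambda_term(x, C=None, epsilon=0.0, chol_lower=None):
    """Normalization signal sqrt(eps + x' C^{-1} x).

    Strictly positive for eps > 0; with eps = 0 it is positively homogeneous
    of degree 1 in x (doubling the stimulus contrast doubles it).  ``x`` may
    be (n,) or (m, n).
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    L = chol_lower if chol_lower is not None else cholesky(
        np.atleast_2d(np.asarray(C, dtype=float)), lower=True)
    Z = solve_triangular(L, X.T, lower=True).T
    lam = np.sqrt(epsilon + np.einsum("ij,ij->i", Z, Z))
    return lam if np.ndim(x) > 1 else float(lam[0])


def _gsm_posterior_mean(x_num, lam, n):
    """Posterior mean of the Gaussian variables behind numerator outputs.

    ``x_num`` are the outputs whose Gaussian estimates are wanted; ``lam`` the
    normalization signal of the full co-assigned vector of dimension ``n``.
    Equals E[x_i / nu | x] under the Rayleigh mixer prior.
    """
    ratio = bessel_ratio((n - 1) / 2.0, (n - 2) / 2.0, lam)
    return x_num * ratio / np.sqrt(lam)


def estimate_coassigned(k, S_g, C_cs, epsilon=1e-10):
    """Center estimates when the center and one surround group share a mixer."""
    k = np.asarray(k, dtype=float)
    x = np.concatenate([k, np.asarray(S_g, dtype=float)])
    n = x.size
    lam = lambda_term(x, C_cs, epsilon)
    return _gsm_posterior_mean(k, lam, n)


def estimate_independent(k, C_c, epsilon=1e-10):
    """Center estimates when no surround group is co-assigned."""
    k = np.asarray(k, dtype=float)
    lam = lambda_term(k, C_c, epsilon)
    return _gsm_posterior_mean(k, lam, k.size)


def _log_posteriors(X, params: MGSMParams):
    comps = component_log_densities(X, params)
    with np.errstate(divide="ignore"):
        lp = np.log(params.priors)[None, :] + comps
    norm = logsumexp(lp, axis=1, keepdims=True)
    if not np.isfinite(norm).all():
        raise ValueError("degenerate input: all component likelihoods vanish")
    return lp - norm


def posterior_components(k, S, params: MGSMParams) -> np.ndarray:
    """Posterior probability of each co-assignment configuration (Bayes rule)."""
    x = np.concatenate([np.ravel(k), np.ravel(S)])
    if params.forced_component is not None:
        q = np.zeros(params.n_groups + 1)
        q[params.forced_component] = 1.0
        return q
    return np.exp(_log_posteriors(x[None, :], params)[0])


def _batch_infer(X, params: MGSMParams):
    """Vectorized posterior, estimates and responses for (m, n_total) outputs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = X.shape[0]
    G, nk = params.n_groups, params.n_center
    eps = params.epsilon
    if params.forced_component is not None:
        q = np.zeros((m, G + 1))
        q[:, params.forced_component] = 1.0
    else:
        q = np.exp(_log_posteriors(X, params))

    K = params.center_block(X)
    lam_c = lambda_term(K, epsilon=eps, chol_lower=params.chol("C_c"))
    est = np.empty((m, G + 1, nk))
    est[:, 0, :] = K * (bessel_ratio((nk - 1) / 2.0, (nk - 2) / 2.0, lam_c)
                        / np.sqrt(lam_c))[:, None]
    n_joint = nk + params.group_size
    lam_cs = np.empty((m, G))
    for g in range(G):
        xg = params.joint_block(X, g)
        lam = lambda_term(xg, epsilon=eps, chol_lower=params.chol(f"C_cs[{g}]"))
        lam_cs[:, g] = lam
        est[:, g + 1, :] = K * (
            bessel_ratio((n_joint - 1) / 2.0, (n_joint - 2) / 2.0, lam)
            / np.sqrt(lam))[:, None]
    g_hat = np.einsum("mc,mci->mi", q, est)
    n_or = nk // 2
    resp = np.sqrt(g_hat[:, 0::2] ** 2 + g_hat[:, 1::2] ** 2)
    assert resp.shape == (m, n_or)
    return q, g_hat, resp, lam_c, lam_cs


def respond(out, params: MGSMParams) -> InferenceResult:
    """Model response to one set of RF outputs.

    ``out`` may be an :class:`~mgsm.filterbank.RFOutputs` or a flat vector.
    The response per orientation is the quadrature (root-sum-of-squares)
    combination of the even- and odd-phase posterior-mean estimates, hence
    invariant to stimulus spatial phase.
    """
    x = getattr(out, "vector", out)
    q, g_hat, resp, lam_c, lam_cs = _batch_infer(np.asarray(x)[None, :], params)
    return InferenceResult(
        posterior=q[0], g_hat=g_hat[0], response=resp[0],
        lambdas={"lambda_c": float(lam_c[0]), "lambda_cs": lam_cs[0]})


def respond_batch(X, params: MGSMParams) -> np.ndarray:
    """(m, n_orientations) phase-invariant responses for a batch of outputs."""
    return _batch_infer(X, params)[2]


def modulation_index(r_co, r_no) -> float:
    """Percent surround modulation, 100 * (R_co - R_no) / R_no.

    Negative values are suppression, positive facilitation.
    """
    if r_no <= 0:
        raise ValueError("reference response must be positive")
    return 100.0 * (r_co - r_no) / r_no
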