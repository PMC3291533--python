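"""Unsupervised fitting of the MGSM by generalized EM (GEM).

A full GEM cycle is a sequence of sub-cycles, each consisting of a full
E-step (posterior responsibilities over the five co-assignment components)
and a partial M-step that updates a single covariance matrix by conjugate
gradients on the expected complete-data log-likelihood; priors are updated in
closed form as mean responsibilities.  Covariances are parameterized by their
lower Cholesky factor with a log-transformed diagonal, so every iterate is
positive-definite without constraints.

Because each covariance enters the complete-data likelihood only through
responsibility-weighted GSM factors, each partial M-step reduces to a
weighted GSM maximum-likelihood problem:

    C_c      weights r_i0            (independent component only)
    C_cs[g]  weights r_i(g+1)        (the co-assigned component g)
    C_s[g]   weights 1 - r_i(g+1)    (every component except g's co-assignment)
"""
from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.special import logsumexp

from .core import MGSMParams, bessel_ratio, component_log_densities, log_kv


@dataclass
class TrainingConfig:
    n_patches: int = 25000
    patch_size: int = 23
    max_em_cycles: int = 200
    loglik_rel_tol: float = 1e-6
    n_restarts: int = 1
    seed: int = 0
    cg_max_iter: int = 20
    renormalize: bool = True
    epsilon: float = 1e-10
    init_jitter: float = 1e-3

    def __post_init__(self):
        if min(self.n_patches, self.patch_size, self.max_em_cycles,
               self.n_restarts, self.cg_max_iter) < 1:
            raise ValueError("counts must be positive")
        if self.loglik_rel_tol <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class TrainingTrace:
    loglik: list = field(default_factory=list)      # per full GEM cycle
    priors: list = field(default_factory=list)
    converged: bool = False

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"cycle": np.arange(len(self.loglik)),
                           "loglik": self.loglik})
        pr = np.asarray(self.priors)
        for j in range(pr.shape[1] if pr.size else 0):
            df[f"prior_{j}"] = pr[:, j]
        return df


# --- E-step ---------------------------------------------------------------

def e_step(X, params: MGSMParams) -> np.ndarray:
    """Responsibilities (m, G+1): posterior over the assignment variable."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    comps = component_log_densities(X, params)
    with np.errstate(divide="ignore"):
        lp = np.log(params.priors)[None, :] + comps
    lp -= logsumexp(lp, axis=1, keepdims=True)
    return np.exp(lp)


def total_log_likelihood(X, params: MGSMParams) -> float:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    comps = component_log_densities(X, params)
    with np.errstate(divide="ignore"):
        lp = np.log(params.priors)[None, :] + comps
    return float(logsumexp(lp, axis=1).sum())


# --- weighted GSM likelihood in Cholesky parameterization ------------------

def _theta_from_chol(L):
    n = L.shape[0]
    idx = np.tril_indices(n, -1)
    return np.concatenate([np.log(np.diag(L)), L[idx]])


def _chol_from_theta(theta, n):
    L = np.zeros((n, n))
    L[np.diag_indices(n)] = np.exp(theta[:n])
    L[np.tril_indices(n, -1)] = theta[n:]
    return L


def weighted_gsm_nll(theta, X, w, epsilon):
    """Negative weighted GSM log-likelihood and its gradient wrt theta.

    ``theta`` parameterizes C = L L' (log-diagonal lower Cholesky).  Constant
    terms independent of C are dropped.  The lam-derivative of the GSM log
    density simplifies via the Bessel recurrence
    K_{a+1} = K_{a-1} + (2a/lam) K_a to

        psi(lam) = (2 - n) / lam - K_{a-1}(lam) / K_a(lam),  a = n/2 - 1.
    """
    m, n = X.shape
    L = _chol_from_theta(theta, n)
    Z = solve_triangular(L, X.T, lower=True, check_finite=False).T
    lam = np.sqrt(epsilon + np.einsum("ij,ij->i", Z, Z))
    lam = np.maximum(lam, 1e-12)
    a = n / 2.0 - 1.0
    W = w.sum()
    logdet = 2.0 * np.log(np.diag(L)).sum()
    ll = (-0.5 * W * logdet + ((1.0 - n / 2.0) * np.log(lam) + log_kv(a, lam)) @ w)

    # gradient wrt C, then chain through C = L L'
    psi = (2.0 - n) / lam - bessel_ratio(a - 1.0, a, lam)
    # dC terms: -(W/2) C^{-1}  and  sum_i w_i psi_i/(2 lam_i) * (-C^{-1}x x'C^{-1})
    Y = solve_triangular(L, Z.T, lower=True, trans=1, check_finite=False).T  # C^{-1} x
    coef = w * psi / (2.0 * lam)
    Gc = -0.5 * W * _chol_inverse_as_cov_inv(L) - (Y.T * coef) @ Y
    # dll/dL = 2 * tril(Gc @ L); diagonal entries get an extra factor L_ii
    GL = 2.0 * np.tril(Gc @ L)
    grad = np.concatenate([np.diag(GL) * np.diag(L),
                           GL[np.tril_indices(n, -1)]])
    return -ll, -grad


def _chol_inverse_as_cov_inv(L):
    n = L.shape[0]
    Linv = solve_triangular(L, np.eye(n), lower=True)
    return Linv.T @ Linv


def _fit_weighted_gsm(C0, X, w, epsilon, max_iter):
    """Conjugate-gradient ascent on the weighted GSM likelihood from C0."""
    n = C0.shape[0]
    L0 = cholesky(C0, lower=True)
    theta0 = _theta_from_chol(L0)
    f0, _ = weighted_gsm_nll(theta0, X, w, epsilon)
    res = minimize(weighted_gsm_nll, theta0, args=(X, w, epsilon),
                   jac=True, method="CG",
                   options={"maxiter": max_iter, "gtol": 1e-5})
    if res.fun <= f0:
        L = _chol_from_theta(res.x, n)
        return L @ L.T, float(-res.fun), float(-f0)
    return C0, float(-f0), float(-f0)


def _cov_names(G):
    return ["C_c"] + [f"C_s[{g}]" for g in range(G)] + \
           [f"C_cs[{g}]" for g in range(G)]


def m_step_partial(X, responsibilities, params: MGSMParams, which_covariance,
                   cg_max_iter=20) -> MGSMParams:
    """One partial M-step: update a single covariance (and the priors).

    The expected complete-data log-likelihood restricted to the chosen
    covariance is ascended by conjugate gradients in the Cholesky
    parameterization; the update is kept only if it does not decrease the
    objective.  Priors are set to the column means of the responsibilities
    (their closed-form maximizer).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    R = np.asarray(responsibilities, dtype=float)
    G = params.n_groups
    new = params.copy(priors=R.mean(axis=0))
    name = which_covariance
    if name == "C_c":
        data, w = params.center_block(X), R[:, 0]
    elif name.startswith("C_s"):
        g = int(name.split("[")[1][:-1])
        data, w = params.group_block(X, g), 1.0 - R[:, g + 1]
    elif name.startswith("C_cs"):
        g = int(name.split("[")[1][:-1])
        data, w = params.joint_block(X, g), R[:, g + 1]
    else:
        raise ValueError(f"unknown covariance {which_covariance!r}")
    if w.sum() < 1e-8:   # component effectively empty; leave covariance alone
        return new
    C_new, _, _ = _fit_weighted_gsm(params.get_cov(name), data, w,
                                    params.epsilon, cg_max_iter)
    if name == "C_c":
        new.C_c = C_new
    elif name.startswith("C_s"):
        new.C_s[g] = C_new
    else:
        new.C_cs[g] = C_new
    return new.copy()  # fresh Cholesky cache


# --- initialization and the main GEM loop ----------------------------------

def _moment_init(X, nk, G, ns, epsilon, jitter, rng=None):
    """Sample-covariance initialization (Cov(x) = E[nu^2] C = 2C for Rayleigh)."""
    def cov(block):
        C = 0.5 * np.cov(block, rowvar=False)
        C += (jitter * np.trace(C) / C.shape[0]) * np.eye(C.shape[0])
        if rng is not None:
            d = np.exp(0.25 * rng.standard_normal(C.shape[0]))
            C = C * np.outer(d, d)
        return C

    C_c = cov(X[:, :nk])
    C_s = np.stack([cov(X[:, nk + g * ns: nk + (g + 1) * ns])
                    for g in range(G)])
    C_cs = np.stack([cov(np.concatenate(
        [X[:, :nk], X[:, nk + g * ns: nk + (g + 1) * ns]], axis=1))
        for g in range(G)])
    priors = np.full(G + 1, 1.0 / (G + 1))
    return MGSMParams(C_c, C_s, C_cs, priors, epsilon=epsilon)


def gem_fit(X, config: TrainingConfig | None = None, n_center=8, n_groups=4,
            verbose=False):
    """Fit MGSM parameters to RF-output vectors by generalized EM.

    ``X`` is (m, n_total).  Runs ``config.n_restarts`` fits from perturbed
    moment initializations and returns the best by final log-likelihood,
    with a :class:`TrainingTrace`.  The log-likelihood is non-decreasing
    across cycles up to the tolerance of the partial conjugate-gradient
    M-steps.
    """
    config = config or TrainingConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m, D = X.shape
    if m == 0:
        raise ValueError("dataset is empty")
    ns = (D - n_center) // n_groups if n_groups else 0
    if n_center + n_groups * ns != D:
        raise ValueError("data dimension incompatible with group structure")

    best = None
    for r in range(config.n_restarts):
        rng = np.random.default_rng(config.seed + 1000 * r)
        params = _moment_init(X, n_center, n_groups, ns, config.epsilon,
                              config.init_jitter, rng if r > 0 else None)
        trace = TrainingTrace()
        prev = -np.inf
        names = _cov_names(n_groups)
        for cycle in range(config.max_em_cycles):
            for name in names:
                R = e_step(X, params)
                params = m_step_partial(X, R, params, name,
                                        cg_max_iter=config.cg_max_iter)
            ll = total_log_likelihood(X, params)
            trace.loglik.append(ll)
            trace.priors.append(params.priors.copy())
            if verbose:
                print(f"restart {r} cycle {cycle}: loglik {ll:.2f}")
            if np.isfinite(prev) and abs(ll - prev) <= config.loglik_rel_tol * abs(prev):
                trace.converged = True
                break
            prev = ll
        if config.renormalize:
            params = renormalize_rotational(params)
        final = total_log_likelihood(X, params)
        if best is None or final > best[2]:
            best = (params, trace, final)
    return best[0], best[1]


# --- rotational renormalization --------------------------------------------

def _center_rotation(nk, steps, n_or):
    """Signed permutation matrix for the center block under layout rotation."""
    n_ph = nk // n_or
    P = np.zeros((nk, nk))
    for o in range(n_or):
        for ph in range(n_ph):
            o_new = (o + steps) % n_or
            s = -1.0 if (ph == 1 and (o + steps) // n_or % 2 == 1) else 1.0
            P[o_new * n_ph + ph, o * n_ph + ph] = s
    return P


def _position_rotation(ns, steps, n_pos):
    n_ph = ns // n_pos
    P = np.zeros((ns, ns))
    for p in range(n_pos):
        for ph in range(n_ph):
            P[((p + steps) % n_pos) * n_ph + ph, p * n_ph + ph] = 1.0
    return P


def _surround_rotation(ns, step, n_pos, n_or):
    """Signed within-group map under ``step`` layout-rotation increments.

    Positions advance around the circle; when the group's orientation wraps
    past 180 degrees (step >= n_or) the odd-phase filters flip sign.
    """
    n_ph = ns // n_pos
    shift = step * n_pos // (2 * n_or)
    P = np.zeros((ns, ns))
    flip = (step // n_or) % 2 == 1
    for p in range(n_pos):
        for ph in range(n_ph):
            s = -1.0 if (flip and ph == 1) else 1.0
            P[((p + shift) % n_pos) * n_ph + ph, p * n_ph + ph] = s
    return P


def renormalize_rotational(params: MGSMParams, n_pos=8) -> MGSMParams:
    """Average the covariances over the layout-rotation group.

    The spatial layout maps onto itself under rotations by 180/n_orientations
    degrees (a cyclic group of order 2*n_or; the elements beyond n_or map each
    orientation group to itself with a half-turn position shift and odd-phase
    sign flips).  After averaging, the joint covariances ``C_cs[g]`` (and
    ``C_s[g]``) are exact rotated copies of a single template, ``C_c`` is
    invariant under the center orientation cycle, and the co-assigned priors
    are equal.  As a result, model responses to rotated copies of a stimulus
    are exactly permuted copies of each other.  The operation is idempotent.
    """
    G, nk, ns = params.n_groups, params.n_center, params.group_size
    n_or = G
    order = 2 * n_or

    def M_joint(step):
        M = np.zeros((nk + ns, nk + ns))
        M[:nk, :nk] = _center_rotation(nk, step, n_or)
        M[nk:, nk:] = _surround_rotation(ns, step, n_pos, n_or)
        return M

    T_cs = np.zeros_like(params.C_cs[0])
    T_s = np.zeros_like(params.C_s[0])
    C_c = np.zeros_like(params.C_c)
    for step in range(order):
        g = step % G
        M = M_joint(step)
        T_cs += M.T @ params.C_cs[g] @ M / order
        Ps = _surround_rotation(ns, step, n_pos, n_or)
        T_s += Ps.T @ params.C_s[g] @ Ps / order
        Pk = _center_rotation(nk, step, n_or)
        C_c += Pk @ params.C_c @ Pk.T / order
    C_cs = np.stack([M_joint(g) @ T_cs @ M_joint(g).T for g in range(G)])
    C_s = np.stack([
        _surround_rotation(ns, g, n_pos, n_or) @ T_s
        @ _surround_rotation(ns, g, n_pos, n_or).T
        for g in range(G)])
    priors = params.priors.copy()
    priors[1:] = priors[1:].mean()
    # exact symmetry (guard against fp asymmetry from the averaging)
    C_c = 0.5 * (C_c + C_c.T)
    C_s = 0.5 * (C_s + np.swapaxes(C_s, 1, 2))
    C_cs = 0.5 * (C_cs + np.swapaxes(C_cs, 1, 2))
    return params.copy(C_c=C_c, C_s=C_s, C_cs=C_cs, priors=priors)


def project_dataset(patches, bank, subtract_mean=True) -> np.ndarray:
    """RF outputs for a stack of training patches (patch mean removed first)."""
    from .filterbank import project_patches

    patches = np.asarray(patches, dtype=float)
    if subtract_mean:
        patches = patches - patches.mean(axis=(1, 2), keepdims=True)
    return project_patches(patches, bank)
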