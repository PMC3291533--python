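"""Mixture-of-Gaussian-scale-mixtures (MGSM) probability model.

A Gaussian scale mixture (GSM) vector is ``x = nu * g`` with ``g ~ N(0, C)``
and a positive mixer ``nu`` shared across coordinates.  With a Rayleigh prior
``p(nu) = nu * exp(-nu**2 / 2)`` the marginal density has a closed form in the
modified Bessel function of the second kind:

    p(x) = (2*pi)**(-n/2) |C|**(-1/2) * lam**(1 - n/2) * K_{n/2-1}(lam),
    lam  = sqrt(eps + x' C^{-1} x).

The MGSM used here mixes five such configurations of the 72 filter outputs
(8 center, 4 surround groups of 16): one in which every group has its own
mixer (component 0) and four in which the center shares a mixer with exactly
one surround orientation group (components 1..4).  Groups that do not share a
mixer are independent, so each component density factorizes into GSM factors.

The overall GSM scale is not identifiable jointly with C, so the Rayleigh
scale is fixed to 1 and all scale is absorbed into the covariances.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import gammaln, kve, logsumexp
from scipy.stats import pearsonr

_LOG2 = np.log(2.0)
_SMALL_LAM = 1e-6


def log_kv(order: float, lam) -> np.ndarray:
    """log K_order(lam), stable for tiny and large arguments.

    Uses exponentially scaled Bessel evaluation; below ``lam = 1e-6`` switches
    to the small-argument series K_a(x) ~ Gamma(a)/2 * (2/x)**a (a > 0) or
    K_0(x) ~ -log(x/2) - gamma, where naive evaluation over/underflows.
    """
    scalar = np.isscalar(lam) or np.ndim(lam) == 0
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    out = np.empty_like(lam)
    small = lam < _SMALL_LAM
    big = ~small
    if big.any():
        out[big] = np.log(kve(order, lam[big])) - lam[big]
    if small.any():
        x = np.maximum(lam[small], np.finfo(float).tiny)
        a = abs(order)  # K_{-a} == K_a
        if a > 0:
            out[small] = gammaln(a) - _LOG2 + a * (_LOG2 - np.log(x))
        else:
            out[small] = np.log(-np.log(x / 2.0) - np.euler_gamma)
    return float(out[0]) if scalar else out


def bessel_ratio(num_order: float, den_order: float, lam) -> np.ndarray:
    """K_{num_order}(lam) / K_{den_order}(lam), stable across the range."""
    scalar = np.isscalar(lam) or np.ndim(lam) == 0
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    out = np.empty_like(lam)
    small = lam < _SMALL_LAM
    big = ~small
    if big.any():
        out[big] = kve(num_order, lam[big]) / kve(den_order, lam[big])
    if small.any():
        out[small] = np.exp(log_kv(num_order, lam[small])
                            - log_kv(den_order, lam[small]))
    return float(out[0]) if scalar else out


def gsm_log_density(x, C, rayleigh_scale=1.0, epsilon=0.0) -> np.ndarray:
    """Closed-form log density of a Rayleigh-mixer GSM.

    ``x`` may be a single vector (n,) or a batch (m, n).  Equals
    ``log integral N(x; 0, nu^2 C) Rayleigh(nu) dnu``; a Rayleigh scale s is
    equivalent to using covariance s**2 * C.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    n = C.shape[0]
    if x.shape[1] != n:
        raise ValueError(f"dimension mismatch: x has {x.shape[1]}, C has {n}")
    Ceff = (rayleigh_scale**2) * C
    try:
        L = cholesky(Ceff, lower=True)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"covariance not positive-definite: {err}")
    zz = solve_triangular(L, x.T, lower=True).T
    q = np.einsum("ij,ij->i", zz, zz)
    lam = np.sqrt(epsilon + q)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    a = n / 2.0 - 1.0
    out = (-0.5 * n * np.log(2 * np.pi) - 0.5 * logdet
           + (1.0 - n / 2.0) * np.log(np.maximum(lam, np.finfo(float).tiny))
           + log_kv(a, lam))
    return out if out.size > 1 else float(out[0])


@dataclass(eq=False)
class MGSMParams:
    """Parameters of the mixture: covariances, priors, mixer scale, gain floor.

    ``C_c``: (nk, nk) covariance of the center Gaussian variables.
    ``C_s``: (G, ns, ns) covariance of each surround orientation group.
    ``C_cs``: (G, nk+ns, nk+ns) joint center+surround covariance per group.
    ``priors``: (G+1,) with priors[0] the no-co-assignment component.
    ``forced_component``: when set, inference bypasses the posterior and
    assigns that component with probability 1 (reduced-model ablation).
    """

    C_c: np.ndarray
    C_s: np.ndarray
    C_cs: np.ndarray
    priors: np.ndarray
    rayleigh_scale: float = 1.0
    epsilon: float = 1e-10
    forced_component: int | None = None
    _chol: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.C_c = np.asarray(self.C_c, dtype=float)
        self.C_s = np.asarray(self.C_s, dtype=float)
        self.C_cs = np.asarray(self.C_cs, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        self.validate()

    # --- shape helpers -------------------------------------------------
    @property
    def n_center(self):
        return self.C_c.shape[0]

    @property
    def n_groups(self):
        return self.C_s.shape[0]

    @property
    def group_size(self):
        return self.C_s.shape[1]

    @property
    def n_total(self):
        return self.n_center + self.n_groups * self.group_size

    def center_block(self, X):
        return np.asarray(X)[..., : self.n_center]

    def group_block(self, X, g):
        n0 = self.n_center + g * self.group_size
        return np.asarray(X)[..., n0: n0 + self.group_size]

    def joint_block(self, X, g):
        return np.concatenate(
            [self.center_block(X), self.group_block(X, g)], axis=-1)

    def validate(self):
        G = self.n_groups
        if self.C_cs.shape != (G, self.n_center + self.group_size,
                               self.n_center + self.group_size):
            raise ValueError("C_cs shape inconsistent with C_c / C_s")
        if self.priors.shape != (G + 1,):
            raise ValueError(f"priors must have length {G + 1}")
        if (self.priors < -1e-12).any() or abs(self.priors.sum() - 1) > 1e-8:
            raise ValueError("priors must be nonnegative and sum to 1")
        for name, M in self.named_covariances():
            if not np.allclose(M, M.T, atol=1e-10):
                raise ValueError(f"{name} is not symmetric")
            self.chol(name)  # raises if not PD

    def named_covariances(self):
        yield "C_c", self.C_c
        for g in range(self.n_groups):
            yield f"C_s[{g}]", self.C_s[g]
        for g in range(self.n_groups):
            yield f"C_cs[{g}]", self.C_cs[g]

    def get_cov(self, name):
        if name == "C_c":
            return self.C_c
        kind, idx = name[:-1].split("[")
        idx = int(idx)
        return self.C_s[idx] if kind == "C_s" else self.C_cs[idx]

    def chol(self, name):
        """Cached lower Cholesky factor of a named covariance."""
        if name not in self._chol:
            M = (self.rayleigh_scale**2) * self.get_cov(name)
            try:
                self._chol[name] = cholesky(M, lower=True)
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    f"{name} is not positive-definite: {err}")
        return self._chol[name]

    def copy(self, **updates):
        kw = dict(C_c=self.C_c.copy(), C_s=self.C_s.copy(),
                  C_cs=self.C_cs.copy(), priors=self.priors.copy(),
                  rayleigh_scale=self.rayleigh_scale, epsilon=self.epsilon,
                  forced_component=self.forced_component)
        kw.update(updates)
        return MGSMParams(**kw)


def _gsm_log_density_chol(X, L, n, epsilon):
    Z = solve_triangular(L, np.atleast_2d(X).T, lower=True).T
    lam = np.sqrt(epsilon + np.einsum("ij,ij->i", Z, Z))
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return (-0.5 * n * np.log(2 * np.pi) - 0.5 * logdet
            + (1.0 - n / 2.0) * np.log(np.maximum(lam, np.finfo(float).tiny))
            + log_kv(n / 2.0 - 1.0, lam))


def component_log_densities(X, params: MGSMParams) -> np.ndarray:
    """(m, G+1) log densities of the outputs under each mixture component.

    Component 0 factorizes fully (center and every surround group each under
    their own mixer); component g+1 couples the center with surround group g
    and leaves the other groups independent.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.n_total:
        raise ValueError(
            f"outputs have dimension {X.shape[1]}, params expect {params.n_total}")
    eps = params.epsilon
    G = params.n_groups
    g_c = _gsm_log_density_chol(params.center_block(X), params.chol("C_c"),
                                params.n_center, eps)
    g_s = np.stack([
        _gsm_log_density_chol(params.group_block(X, g), params.chol(f"C_s[{g}]"),
                              params.group_size, eps)
        for g in range(G)], axis=1)
    g_cs = np.stack([
        _gsm_log_density_chol(params.joint_block(X, g), params.chol(f"C_cs[{g}]"),
                              params.n_center + params.group_size, eps)
        for g in range(G)], axis=1)
    s_all = g_s.sum(axis=1)
    comps = np.empty((X.shape[0], G + 1))
    comps[:, 0] = g_c + s_all
    for g in range(G):
        comps[:, g + 1] = g_cs[:, g] + s_all - g_s[:, g]
    return comps


def mgsm_log_density(outputs, params: MGSMParams) -> np.ndarray:
    """Log density of RF outputs under the full mixture (log-sum-exp)."""
    X = getattr(outputs, "vector", outputs)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    comps = component_log_densities(X, params)
    with np.errstate(divide="ignore"):
        lp = np.log(params.priors)
    out = logsumexp(lp[None, :] + comps, axis=1)
    return out if out.size > 1 else float(out[0])


# --- sampling -----------------------------------------------------------

def sample_gsm(C, n_samples, seed=0, rayleigh_scale=1.0) -> np.ndarray:
    """Draw ``n_samples`` vectors nu * g with g ~ N(0, C), nu ~ Rayleigh."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    L = cholesky(C, lower=True)
    g = rng.standard_normal((n_samples, C.shape[0])) @ L.T
    nu = rng.rayleigh(scale=rayleigh_scale, size=n_samples)
    return nu[:, None] * g


def sample_mgsm(params: MGSMParams, n_samples, seed=0):
    """Sample RF-output vectors and their true component labels.

    Under component 0 the center and each surround group get independent
    mixers; under component g+1 the center and group g share one mixer while
    the other groups keep their own.
    """
    rng = np.random.default_rng(seed)
    G, nk, ns = params.n_groups, params.n_center, params.group_size
    labels = rng.choice(G + 1, size=n_samples, p=params.priors)
    X = np.empty((n_samples, params.n_total))
    s = params.rayleigh_scale
    for comp in range(G + 1):
        idx = np.nonzero(labels == comp)[0]
        if idx.size == 0:
            continue
        m = idx.size
        block = np.empty((m, params.n_total))
        if comp == 0:
            block[:, :nk] = sample_gsm(params.C_c, m, rng, s)
            for g in range(G):
                block[:, nk + g * ns: nk + (g + 1) * ns] = sample_gsm(
                    params.C_s[g], m, rng, s)
        else:
            g = comp - 1
            joint = sample_gsm(params.C_cs[g], m, rng, s)
            block[:, :nk] = joint[:, :nk]
            block[:, nk + g * ns: nk + (g + 1) * ns] = joint[:, nk:]
            for h in range(G):
                if h != g:
                    block[:, nk + h * ns: nk + (h + 1) * ns] = sample_gsm(
                        params.C_s[h], m, rng, s)
        X[idx] = block
    return X, labels


# --- diagnostics ---------------------------------------------------------

@dataclass
class ConditionalHistogram:
    """2-D histogram of a given b, with per-column statistics."""

    hist: np.ndarray          # (n_bins_a, n_bins_b), columns rescaled to [0,1]
    a_edges: np.ndarray
    b_edges: np.ndarray
    column_mean: np.ndarray   # mean of a per b-bin
    column_std: np.ndarray    # std of a per b-bin
    pearson_r: float
    counts: np.ndarray


def conditional_histogram(outputs_a, outputs_b, n_bins=25) -> ConditionalHistogram:
    """Histogram of one RF output conditioned on another.

    Each column (one bin of ``outputs_b``) is rescaled independently to the
    full intensity range, which visualizes the conditional distribution of
    ``outputs_a`` and makes variance (bowtie) dependencies apparent.
    """
    a = np.asarray(outputs_a, dtype=float).ravel()
    b = np.asarray(outputs_b, dtype=float).ravel()
    if a.size == 0 or a.size != b.size:
        raise ValueError("paired nonempty samples required")
    H, a_edges, b_edges = np.histogram2d(a, b, bins=n_bins)
    counts = H.sum(axis=0)
    col_max = np.where(H.max(axis=0) > 0, H.max(axis=0), 1.0)
    hist = H / col_max[None, :]
    which = np.clip(np.digitize(b, b_edges) - 1, 0, n_bins - 1)
    col_mean = np.full(n_bins, np.nan)
    col_std = np.full(n_bins, np.nan)
    for j in range(n_bins):
        sel = which == j
        if sel.sum() > 1:
            col_mean[j] = a[sel].mean()
            col_std[j] = a[sel].std()
    r = float(pearsonr(a, b).statistic)
    return ConditionalHistogram(hist, a_edges, b_edges, col_mean, col_std,
                                r, counts)
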