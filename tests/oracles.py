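"""Independent quadrature oracles for the Rayleigh-mixer GSM.

These integrate over the mixer numerically (log-domain, over t = log nu) and
never touch the closed-form Bessel expressions they are used to check.
"""
import numpy as np
from scipy.integrate import quad

_T_LO, _T_HI = -14.0, 7.0


def _log_integrand(t, n, q, extra_inv_nu=0):
    nu = np.exp(t)
    return (np.log(nu) - nu**2 / 2.0            # Rayleigh(1) prior
            - n * np.log(nu) - q / (2.0 * nu**2)  # N(x; 0, nu^2 C) kernel
            + t                                   # d nu = nu dt
            - extra_inv_nu * t)                   # optional 1/nu moment


def _log_quad(n, q, extra_inv_nu=0):
    ts = np.linspace(_T_LO, _T_HI, 2001)
    vals = _log_integrand(ts, n, q, extra_inv_nu)
    M = vals.max()
    v, _ = quad(lambda t: np.exp(_log_integrand(t, n, q, extra_inv_nu) - M),
                _T_LO, _T_HI, limit=400)
    return M + np.log(v)


def gsm_log_density_quadrature(x, C):
    """log p(x) for x = nu * g, g ~ N(0, C), nu ~ Rayleigh(1)."""
    x = np.asarray(x, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    n = x.size
    q = float(x @ np.linalg.solve(C, x))
    sign, logdet = np.linalg.slogdet(C)
    const = -0.5 * n * np.log(2 * np.pi) - 0.5 * logdet
    return const + _log_quad(n, q)


def gsm_posterior_mean_quadrature(x, C, index):
    """E[g_index | x] = x_index * E[1/nu | x] by 1-D quadrature."""
    x = np.asarray(x, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    n = x.size
    q = float(x @ np.linalg.solve(C, x))
    return x[index] * np.exp(_log_quad(n, q, extra_inv_nu=1)
                             - _log_quad(n, q, extra_inv_nu=0))
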