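import numpy as np
import pytest
from scipy.special import logsumexp

from mgsm.core import (MGSMParams, component_log_densities,
                       conditional_histogram, gsm_log_density,
                       mgsm_log_density, sample_gsm, sample_mgsm)
from mgsm.filterbank import project_patches
from mgsm.stimuli import sample_patches, white_noise

from oracles import gsm_log_density_quadrature


def _random_cov(n, rng, jitter=0.1):
    A = rng.standard_normal((n, n + 2))
    return A @ A.T / (n + 2) + jitter * np.eye(n)


@pytest.mark.parametrize("n", [1, 2, 8, 24])
def test_gsm_density_matches_quadrature_oracle(n):
    rng = np.random.default_rng(n)
    C = _random_cov(n, rng)
    for _ in range(20):
        x = rng.standard_normal(n) * rng.uniform(0.3, 3.0)
        closed = gsm_log_density(x, C)
        oracle = gsm_log_density_quadrature(x, C)
        assert closed == pytest.approx(oracle, rel=1e-6, abs=1e-8)


def test_gsm_density_symmetry_and_normalization():
    rng = np.random.default_rng(0)
    C = _random_cov(3, rng)
    for _ in range(5):
        x = rng.standard_normal(3)
        assert gsm_log_density(x, C) == pytest.approx(
            gsm_log_density(-x, C), abs=1e-12)
    xs = np.linspace(-50, 50, 200001)
    dens = np.exp(gsm_log_density(xs[:, None], np.eye(1)))
    assert np.trapezoid(dens, xs) == pytest.approx(1.0, abs=1e-6)


def test_gsm_density_rejects_bad_inputs():
    with pytest.raises(np.linalg.LinAlgError):
        gsm_log_density(np.ones(2), np.array([[1.0, 2.0], [2.0, 1.0]]))
    with pytest.raises(ValueError, match="dimension"):
        gsm_log_density(np.ones(3), np.eye(2))


def test_mgsm_density_degenerate_mixture_and_bound(params_true):
    rng = np.random.default_rng(1)
    X = rng.normal(0, 0.2, (50, params_true.n_total))
    comps = component_log_densities(X, params_true)
    # prior mass all on the independent component -> exactly its density
    solo = params_true.copy(priors=np.array([1.0, 0, 0, 0, 0.0]))
    assert np.allclose(mgsm_log_density(X, solo), comps[:, 0], atol=1e-10)
    # log-sum-exp bound: mixture density >= max_component (prior-weighted)
    full = mgsm_log_density(X, params_true)
    lower = (np.log(params_true.priors)[None, :] + comps).max(axis=1)
    assert np.all(full >= lower - 1e-12)
    assert np.allclose(full, logsumexp(
        np.log(params_true.priors)[None, :] + comps, axis=1), atol=1e-12)


def test_model_prefers_true_parameters(params_true):
    """Gibbs inequality: average log density is maximal under the truth."""
    X, _ = sample_mgsm(params_true, 5000, seed=4)
    perturbed = params_true.copy(
        C_cs=params_true.C_cs * 1.6,
        priors=np.array([0.1, 0.3, 0.2, 0.2, 0.2]))
    assert mgsm_log_density(X, params_true).mean() > \
        mgsm_log_density(X, perturbed).mean()


def test_sample_gsm_covariance_scaling():
    C = np.array([[1.0, 0.5], [0.5, 2.0]])
    X = sample_gsm(C, 10**6, seed=3)
    # E[nu^2] = 2 for Rayleigh(1)
    rel = np.linalg.norm(np.cov(X.T) - 2 * C) / np.linalg.norm(2 * C)
    assert rel < 0.02


def test_sample_mgsm_component_frequencies(params_true):
    n = 10**5
    _, labels = sample_mgsm(params_true, n, seed=5)
    freq = np.bincount(labels, minlength=5) / n
    # three-sigma binomial band around each prior
    sd = np.sqrt(params_true.priors * (1 - params_true.priors) / n)
    assert np.all(np.abs(freq - params_true.priors) < 3.5 * sd + 1e-12)


def test_bowtie_variance_dependence_in_gsm_samples():
    # co-assigned coordinates with the correlation typical of collinear pairs
    C = np.array([[1.0, 0.4], [0.4, 1.0]])
    X = sample_gsm(C, 200000, seed=6)
    a = np.abs(X[:, 1])
    lo, hi = np.quantile(a, [0.1, 0.9])
    std_top = X[a >= hi, 0].std()
    std_bottom = X[a <= lo, 0].std()
    assert std_top > 2 * std_bottom


def test_conditional_histogram_basics():
    rng = np.random.default_rng(7)
    x = rng.normal(0, 1, 5000)
    ch = conditional_histogram(x, x)
    assert ch.pearson_r == pytest.approx(1.0, abs=1e-12)
    assert ch.hist.max() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        conditional_histogram([], [])


def test_white_noise_filter_correlations(bank):
    """Linear correlation tracks RF overlap on white-noise input."""
    patches = sample_patches([white_noise(256, 0.25, seed=s).pixels
                              for s in range(3)], 20000, 31, seed=8)
    even = bank.kernel("center", 0, 0)

    def outputs(offset_rows):
        W = np.zeros((2, 31, 31))
        W[0, 11:20, 11:20] = even
        W[1, 11 + offset_rows:20 + offset_rows, 11:20] = even
        return patches.reshape(len(patches), -1) @ W.reshape(2, -1).T

    heavy = outputs(3)     # collinear, strong overlap
    none = outputs(10)     # collinear, fully separated
    r_overlap = conditional_histogram(heavy[:, 0], heavy[:, 1]).pearson_r
    r_apart = conditional_histogram(none[:, 0], none[:, 1]).pearson_r
    assert r_overlap > 0.2
    assert abs(r_apart) < 0.05


def test_params_validation():
    with pytest.raises(ValueError, match="priors"):
        MGSMParams(np.eye(2), np.eye(2)[None].repeat(4, 0),
                   np.eye(4)[None].repeat(4, 0),
                   np.array([0.5, 0.5, 0.0, 0.0, 0.5]))


def test_density_properties_random_inputs():
    """Property check: symmetry and mixer-scale equivalence of the GSM density
    on randomized inputs."""
    from hypothesis import given, settings, strategies as st

    rng = np.random.default_rng(12)
    C = _random_cov(4, rng)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=4),
           st.floats(0.2, 5.0))
    def check(xs, s):
        x = np.asarray(xs)
        assert gsm_log_density(x, C) == pytest.approx(
            gsm_log_density(-x, C), abs=1e-10)
        # Rayleigh scale s is the same model as covariance s^2 C
        assert gsm_log_density(x, C, rayleigh_scale=s) == pytest.approx(
            gsm_log_density(x, s**2 * C), abs=1e-9)

    check()
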