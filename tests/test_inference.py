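import numpy as np
import pytest

from mgsm.filterbank import project
from mgsm.inference import (estimate_coassigned, estimate_independent,
                            lambda_term, modulation_index,
                            posterior_components, respond, respond_batch)
from mgsm.stimuli import grating

from oracles import gsm_posterior_mean_quadrature


def _random_cov(n, rng, jitter=0.1):
    A = rng.standard_normal((n, n + 2))
    return A @ A.T / (n + 2) + jitter * np.eye(n)


def test_lambda_term_closed_cases():
    assert lambda_term(np.array([3.0, 4.0]), np.eye(2), epsilon=0.0) == \
        pytest.approx(5.0, abs=1e-12)
    assert lambda_term(np.zeros(4), np.eye(4), epsilon=1e-10) == \
        pytest.approx(1e-5, abs=1e-12)


def test_lambda_homogeneity():
    rng = np.random.default_rng(0)
    C = _random_cov(5, rng)
    x = rng.standard_normal(5)
    assert lambda_term(7.0 * x, C, epsilon=0.0) == pytest.approx(
        7.0 * lambda_term(x, C, epsilon=0.0), rel=1e-12)


@pytest.mark.parametrize("n_total,n_center", [(2, 1), (8, 8), (24, 8)])
def test_estimates_match_quadrature_oracle(n_total, n_center):
    rng = np.random.default_rng(n_total)
    C = _random_cov(n_total, rng)
    for _ in range(20):
        x = rng.standard_normal(n_total) * rng.uniform(0.3, 2.0)
        if n_total == n_center:
            est = estimate_independent(x, C, epsilon=0.0)
        else:
            est = estimate_coassigned(x[:n_center], x[n_center:], C,
                                      epsilon=0.0)
        for i in range(n_center):
            oracle = gsm_posterior_mean_quadrature(x, C, i)
            assert est[i] == pytest.approx(oracle, rel=1e-6, abs=1e-10)


def test_zero_center_gives_zero_estimate():
    C = np.eye(10)
    est = estimate_coassigned(np.zeros(4), np.ones(6), C)
    assert np.allclose(est, 0.0)


def test_stronger_surround_decreases_coassigned_estimate():
    rng = np.random.default_rng(2)
    C = _random_cov(10, rng)
    k = rng.standard_normal(4)
    S = rng.standard_normal(6)
    prev = estimate_coassigned(k, S, C, epsilon=0.0)
    for scale in (2.0, 4.0, 8.0):
        cur = estimate_coassigned(k, scale * S, C, epsilon=0.0)
        assert np.all(np.abs(cur) < np.abs(prev))
        prev = cur


def test_posterior_normalization_many_inputs(params_true):
    rng = np.random.default_rng(3)
    X = rng.normal(0, 0.3, (10**4, params_true.n_total))
    from mgsm.inference import _log_posteriors

    q = np.exp(_log_posteriors(X, params_true))
    assert np.all(np.abs(q.sum(axis=1) - 1.0) < 1e-10)
    assert q.min() >= 0.0


def test_symmetric_input_gives_equal_coassignment_posteriors():
    """With identity covariances, equal priors and an input that treats all
    surround groups identically, the four co-assignment posteriors agree."""
    from mgsm.core import MGSMParams

    params = MGSMParams(np.eye(8), np.stack([np.eye(16)] * 4),
                        np.stack([np.eye(24)] * 4), np.full(5, 0.2))
    k = np.full(8, 0.5)
    S = np.full((4, 16), 0.3)
    q = posterior_components(k, S, params)
    assert q.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(q[1:], q[1], atol=1e-12)


def test_respond_phase_invariance(bank, params_true):
    responses = []
    for phase in (0.0, 90.0, 45.0):
        out = project(grating(21, 0.6, 0.0, bank.spec.peak_sf, phase, 23), bank)
        responses.append(respond(out, params_true).response[0])
    assert max(responses) - min(responses) < 0.01 * max(responses)


def test_respond_batch_matches_single(bank, params_true):
    rng = np.random.default_rng(5)
    X = rng.normal(0, 0.2, (7, 72))
    batch = respond_batch(X, params_true)
    for i in range(7):
        single = respond(X[i], params_true)
        assert np.allclose(batch[i], single.response, atol=1e-12)
        assert np.all(single.response >= 0)
        assert single.posterior.sum() == pytest.approx(1.0, abs=1e-10)


def test_rotated_stimulus_permutes_responses(bank, params_true):
    """90-deg rotation permutes the orientation responses exactly."""
    stim = grating(15, 0.7, 30.0, bank.spec.peak_sf, 20.0, 23)
    r0 = respond(project(stim.pixels, bank), params_true)
    r90 = respond(project(np.rot90(stim.pixels), bank), params_true)
    assert np.allclose(r90.response, np.roll(r0.response, 2), atol=1e-8)
    # posteriors permute across the co-assigned components as well
    assert np.allclose(r90.posterior[1:], np.roll(r0.posterior[1:], 2),
                       atol=1e-8)
    assert r90.posterior[0] == pytest.approx(r0.posterior[0], abs=1e-8)


def test_modulation_index():
    assert modulation_index(1.0, 1.0) == 0.0
    assert modulation_index(0.84, 1.0) == pytest.approx(-16.0)
    with pytest.raises(ValueError):
        modulation_index(1.0, 0.0)


def test_suppression_facilitation_crossover(params_true):
    """For a fixed center drive, weak surrounds facilitate and strong
    surrounds suppress, with a zero crossing in between."""
    rng = np.random.default_rng(6)
    C = params_true.C_cs[0]
    k = 0.4 * np.array([1.0, 0.6, 0, 0, 0, 0, 0, 0])
    r_no = np.abs(estimate_independent(k, params_true.C_c)[0])
    direction = np.abs(rng.standard_normal(16))
    mods = []
    for s in np.linspace(0.01, 3.0, 40):
        r_co = np.abs(estimate_coassigned(k, s * direction, C)[0])
        mods.append(modulation_index(r_co, r_no))
    mods = np.array(mods)
    assert mods[0] > 0          # weak surround facilitates
    assert mods[-1] < 0         # strong surround suppresses
    assert np.any(np.diff(np.sign(mods)) != 0)
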