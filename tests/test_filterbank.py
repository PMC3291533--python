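import numpy as np
import pytest

from mgsm.filterbank import (FilterBankSpec, GeometryError, build_filterbank,
                             project, project_patches, tuning_curves)
from mgsm.stimuli import grating, white_noise


def test_bank_counts_and_normalization(bank):
    spec = bank.spec
    assert bank.n_filters == 72
    assert (bank.group_index == -1).sum() == 8
    assert spec.n_surround_positions * len(spec.orientations) * \
        len(spec.phases) == 64
    norms = np.linalg.norm(bank.kernels.reshape(bank.n_filters, -1), axis=1)
    assert np.allclose(norms, 1.0, atol=1e-12)
    sums = bank.kernels.reshape(bank.n_filters, -1).sum(axis=1)
    assert np.max(np.abs(sums)) < 1e-12


def test_quadrature_pairs_orthogonal(bank):
    for o in range(4):
        even = bank.kernel("center", o, 0)
        odd = bank.kernel("center", o, 1)
        assert abs((even * odd).sum()) < 1e-8


def test_degenerate_bank_single_kernel():
    spec = FilterBankSpec(orientations=(0.0,), phases=("even",),
                          n_surround_positions=0, patch_size=9)
    dbank = build_filterbank(spec)
    assert dbank.n_filters == 1


def test_patch_size_too_small_raises():
    with pytest.raises(GeometryError, match="21"):
        FilterBankSpec(patch_size=15)


def test_peak_spatial_frequency_and_bandwidth(bank):
    _, summary = tuning_curves(bank)
    assert summary["peak_sf"] == pytest.approx(bank.spec.peak_sf, rel=1e-3)
    assert summary["orientation_halfwidth"] == pytest.approx(
        bank.spec.orientation_halfwidth, abs=0.05)


def test_energy_phase_invariance(bank):
    """Quadrature energy to a grating varies by < 1% over spatial phase."""
    even = bank.kernel("center", 0, 0)
    odd = bank.kernel("center", 0, 1)
    energies = []
    for phase in np.linspace(0, 360, 13):
        g = grating(23, 1.0, 0.0, bank.spec.peak_sf, phase, 23).pixels[7:16, 7:16]
        energies.append(np.hypot((even * g).sum(), (odd * g).sum()))
    energies = np.array(energies)
    assert (energies.max() - energies.min()) / energies.max() < 0.01


def test_projection_linearity_and_zero_input(bank):
    rng = np.random.default_rng(0)
    img1 = rng.normal(0, 0.3, (31, 31))
    img2 = rng.normal(0, 0.3, (31, 31))
    a, b = 1.7, -0.4
    out = project(a * img1 + b * img2, bank, (15, 15)).vector
    expected = a * project(img1, bank, (15, 15)).vector \
        + b * project(img2, bank, (15, 15)).vector
    assert np.allclose(out, expected, atol=1e-12)
    assert np.allclose(project(np.full((31, 31), 0.37), bank, (15, 15)).vector,
                       0.0, atol=1e-12)


def test_self_projection_is_maximal(bank):
    img = np.zeros((31, 31))
    k = bank.kernel("center", 1, 0)
    img[11:20, 11:20] = k
    out = project(img, bank, (15, 15)).vector
    idx = int(np.argmax(out))
    assert out[idx] == pytest.approx(1.0, abs=1e-12)
    assert np.all(out[np.arange(72) != idx] < 1.0 - 1e-6)


def test_out_of_bounds_projection_raises(bank):
    with pytest.raises(GeometryError, match="bounds"):
        project(np.zeros((23, 23)), bank, (3, 3))


def test_rotation_equivariance_exact(bank):
    img = white_noise(31, 0.3, seed=1).pixels
    out = project(img, bank, (15, 15)).vector
    rotated = project(np.rot90(img), bank, (15, 15)).vector
    perm, sign = bank.rotation_permutation(2)
    predicted = np.empty_like(out)
    predicted[perm] = sign * out
    assert np.allclose(rotated, predicted, atol=1e-12)


def test_rotation_permutation_has_period_eight(bank):
    perm, sign = bank.rotation_permutation(1)
    p = np.arange(bank.n_filters)
    s = np.ones(bank.n_filters)
    for _ in range(8):
        s = s * sign[p]
        p = perm[p]
    assert np.array_equal(p, np.arange(bank.n_filters))
    assert np.allclose(s, 1.0)


def test_project_patches_matches_single_projection(bank):
    rng = np.random.default_rng(3)
    patches = rng.normal(0, 0.2, (5, 23, 23))
    X = project_patches(patches, bank)
    single = project(patches[2], bank).vector
    assert np.allclose(X[2], single, atol=1e-10)


def test_grating_encroachment_on_surround(bank):
    """A 7-px grating reaches the surround RFs; a 5-px one barely does."""
    out5 = project(grating(5, 0.9, 0.0, bank.spec.peak_sf, image_size=23), bank)
    out7 = project(grating(7, 0.9, 0.0, bank.spec.peak_sf, image_size=23), bank)
    assert np.abs(out7.S).max() > 2.5 * np.abs(out5.S).max()
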