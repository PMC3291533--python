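"""Protocol-level checks on the experiment battery (ground-truth fixture
parameters; the trained-parameter battery lives in test_acceptance)."""
import numpy as np
import pytest

from mgsm.experiments import (border_enhancement, flanker_modulation,
                              popout_curve, positional_bias, reduced_model,
                              salience_map, size_tuning, suppression_vector,
                              surround_orientation_tuning, tuning_narrowing)
from mgsm.filterbank import project
from mgsm.inference import respond
from mgsm.stimuli import StimulusImage, bar_array, grating


def test_zero_contrast_surround_leaves_response_unchanged(bank, params_true):
    pb = positional_bias(bank, params_true, arrangements=("collinear",),
                         contrasts=(0.4,), angular_sizes=(90,))
    stim_center = grating(9, 0.4, 0.0, bank.spec.peak_sf, image_size=23)
    r_center = respond(project(stim_center, bank), params_true).response[0]
    assert pb.table.center_alone.iloc[0] == pytest.approx(r_center, rel=1e-9)
    # zero-contrast sectors: suppression ratio is exactly 1
    from mgsm.experiments import _sector_stimulus

    full = _sector_stimulus(bank, 0.4, 0.0, 0.0, 90, 0.0)
    r_full = respond(project(full, bank), params_true).response[0]
    assert r_full / r_center == pytest.approx(1.0, abs=1e-12)


def test_blank_image_gives_zero_salience(bank, params_true):
    blank = StimulusImage(np.zeros((47, 47)), 0.0)
    smap = salience_map(blank, bank, params_true)
    assert np.allclose(smap.salience, 0.0, atol=1e-12)


def test_homogeneous_texture_salience_uniform(bank, params_true):
    margin = bank.footprint_radius() + 1
    stim = bar_array(np.zeros((7, 7)), margin=margin)
    smap = salience_map(stim, bank, params_true, grid_spacing=6,
                        origin=(margin, margin))
    interior = smap.salience[2:-2, 2:-2]
    assert (interior.max() - interior.min()) / interior.max() < 0.01


def test_popout_zero_contrast_is_background(bank, params_true):
    pc = popout_curve(bank, params_true, orientation_contrasts=(0,))
    row = pc.table.iloc[0]
    assert row.target_salience == pytest.approx(row.background_salience,
                                                rel=0.01)


def test_texture_enhancement_zero_by_definition(bank, params_true):
    be = border_enhancement(bank, params_true)
    assert be.summary["txt_enhancement"] == 0.0
    txt_row = be.table[be.table.label == "txt"]
    assert txt_row.enhancement.iloc[0] == 0.0


def test_reduced_models_preserve_center_only_responses(params_true):
    """With silent surround outputs, ablations change nothing about the
    forced/diagonal component's center estimate sign structure."""
    x = np.zeros(72)
    x[0], x[1] = 0.4, -0.2
    full = respond(x, params_true)
    fixed = respond(x, reduced_model(params_true, "fixed_assignment"))
    # forced co-assignment with a silent surround equals the co-assigned
    # component's own estimate; responses stay finite and nonnegative
    assert np.all(fixed.response >= 0)
    assert fixed.posterior[1] == 1.0
    diag = respond(x, reduced_model(params_true, "diagonal_covariance"))
    assert np.all(diag.response >= 0)
    with pytest.raises(ValueError):
        reduced_model(params_true, "nonsense")


def test_suppression_vector_points_at_collinear_positions(bank, params_true):
    pb = positional_bias(bank, params_true, arrangements=("collinear",),
                         contrasts=(0.3,), angular_sizes=(60,),
                         polar_contrast=0.3)
    sv = suppression_vector(pb.extras["polar"])
    # for a vertical unit the most suppressive sectors sit on the vertical
    # axis (position angle near 0 mod 180)
    assert min(sv["angle"], 180 - sv["angle"]) < 30
    assert 0 <= sv["orientation_bias"] <= 1


def test_experiment_results_are_deterministic(bank, params_true):
    a = size_tuning(bank, params_true, contrasts=(0.2, 0.6),
                    diameters=(5, 9, 13))
    b = size_tuning(bank, params_true, contrasts=(0.2, 0.6),
                    diameters=(5, 9, 13))
    assert a.table.equals(b.table)
    assert a.meta["params_hash"] == b.meta["params_hash"]


def test_rotating_protocol_rotates_outcomes(bank, params_true):
    """A horizontal-unit size-tuning run equals the vertical one exactly."""
    v = size_tuning(bank, params_true, contrasts=(0.2, 0.7),
                    diameters=(5, 9, 13, 17), orientation=0.0)
    h = size_tuning(bank, params_true, contrasts=(0.2, 0.7),
                    diameters=(5, 9, 13, 17), orientation=90.0)
    # responses of the vertical unit to vertical stimuli == horizontal unit
    # to horizontal stimuli, by rotational consistency of the parameters
    rows_v = v.table.response.to_numpy()
    size = bank.spec.patch_size
    rows_h = []
    for _, row in h.table.iterrows():
        out = project(grating(int(row.diameter), row.contrast, 90.0,
                              bank.spec.peak_sf, image_size=size), bank)
        rows_h.append(respond(out, params_true).response[2])
    assert np.allclose(rows_v, rows_h, atol=1e-8)
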