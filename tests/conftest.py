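import numpy as np
import pytest

from mgsm import (TrainingConfig, build_filterbank, gem_fit, sample_mgsm,
                  sample_patches, structured_params)
from mgsm.fixtures import pseudo_natural_image
from mgsm.training import project_dataset

RECOVERY_SEED = 11
RECOVERY_N = 25000


@pytest.fixture(scope="session")
def bank():
    return build_filterbank()


@pytest.fixture(scope="session")
def params_true():
    return structured_params()


@pytest.fixture(scope="session")
def recovery_data(params_true):
    X, labels = sample_mgsm(params_true, RECOVERY_N, seed=RECOVERY_SEED)
    return X, labels


@pytest.fixture(scope="session")
def trained_params(recovery_data):
    """Parameters fit by GEM to the synthetic MGSM fixture (shared run).

    This single unsupervised fit backs both the parameter-recovery checks and
    the simulated-experiment battery.
    """
    X, _ = recovery_data
    cfg = TrainingConfig(max_em_cycles=40, loglik_rel_tol=1e-6, seed=0,
                         cg_max_iter=10, renormalize=True)
    params, trace = gem_fit(X, cfg)
    return params, trace


@pytest.fixture(scope="session")
def natural_images():
    return [pseudo_natural_image(256, seed=10 + i) for i in range(4)]


@pytest.fixture(scope="session")
def natural_outputs(natural_images, bank):
    patches = sample_patches(natural_images, 20000, bank.spec.patch_size,
                             seed=7)
    return project_dataset(patches, bank)


@pytest.fixture(scope="session")
def natural_trained_params(natural_images, bank):
    """Parameters fit to the pseudo-natural image fixture (small smoke fit)."""
    patches = sample_patches(natural_images, 5000, bank.spec.patch_size,
                             seed=5)
    X = project_dataset(patches, bank)
    cfg = TrainingConfig(n_patches=5000, max_em_cycles=12,
                         loglik_rel_tol=1e-5, seed=0, cg_max_iter=8)
    params, trace = gem_fit(X, cfg)
    return params, trace
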