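"""Unsupervised GEM fit on synthetic contour-rich images (small smoke run).

Samples patches from the pseudo-natural image generator, projects them onto
the filter bank, and fits the mixture by generalized EM.  Prints the fitted
component priors, the log-likelihood trace, and the learned collinear
covariance signature.
"""
import numpy as np

from mgsm import TrainingConfig, build_filterbank, gem_fit, sample_patches
from mgsm.fixtures import pseudo_natural_image
from mgsm.training import project_dataset

bank = build_filterbank()
images = [pseudo_natural_image(256, seed=10 + i) for i in range(4)]
patches = sample_patches(images, 4000, bank.spec.patch_size, seed=5)
X = project_dataset(patches, bank)

cfg = TrainingConfig(n_patches=4000, max_em_cycles=10, cg_max_iter=8,
                     loglik_rel_tol=1e-5, seed=0)
params, trace = gem_fit(X, cfg)

print("log-likelihood per cycle:",
      [f"{v:.0f}" for v in trace.loglik])
print("fitted priors (independent, 4x co-assigned):",
      np.round(params.priors, 3))
C = params.C_cs[0]
print(f"vertical co-assigned component: center var {C[0, 0]:.4f}, "
      f"collinear surround var {C[8, 8]:.4f}, "
      f"parallel surround var {C[12, 12]:.4f}")
print(f"center-collinear covariance {C[0, 8]:.4f} "
      f"vs center-parallel {C[0, 12]:.4f}")
# As in natural scenes, the fitted co-assigned covariance couples the center
# to its collinear neighbors more strongly than to its parallel ones, and the
# log-likelihood increases monotonically across GEM cycles.
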