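# Methods

## The model

The package implements a generative model of oriented filter ("receptive
field", RF) outputs in image patches and derives V1-like responses from exact
Bayesian inference in it.

A Gaussian scale mixture (GSM) describes a vector of filter outputs as
`x = nu * g`, where `g ~ N(0, C)` is a local Gaussian vector and `nu` is a
positive *mixer* shared by all coordinates — a global quantity such as local
contrast that varies smoothly over space. The shared mixer produces the
variance ("bowtie") dependencies between filter outputs that natural images
show; the covariance `C` produces the linear correlations (strongest between
collinear filters, reflecting contours).

With a Rayleigh prior `p(nu) = nu * exp(-nu^2 / 2)` the GSM marginal has a
closed form in the modified Bessel function of the second kind `K_a`:

    p(x) = (2 pi)^(-n/2) |C|^(-1/2) lambda^(1 - n/2) K_{n/2-1}(lambda),
    lambda = sqrt(eps + x' C^{-1} x),

and the posterior mean of the Gaussian variables — the quantity interpreted
as firing rate — is divisive normalization with a Bessel correction:

    E[g_i | x] = x_i / sqrt(lambda) * K_{(n-1)/2}(lambda) / K_{(n-2)/2}(lambda).

Both expressions were derived from the generative definition and are verified
in the test suite against one-dimensional quadrature over the mixer (relative
error < 1e-6 in 1, 2, 8 and 24 dimensions). The Rayleigh scale is fixed to 1:
a free scale is not identifiable jointly with `C`, so all scale lives in the
covariances.

The full model is a mixture of GSM configurations (MGSM) over 72 filter
outputs: a center group `k` (4 orientations x 2 phases at one position) and
four surround groups `S_theta` (one orientation each, 2 phases, 8 positions
on a radius-6 circle). Five mixture components encode *which groups share a
mixer*: under component 0 the center and every surround group have their own
independent mixers; under component `theta` the center shares one mixer with
surround group `theta` (they are *co-assigned*) while the other groups stay
independent. Every component density therefore factorizes into GSM factors,
evaluated in the log domain with log-sum-exp.

Inference of the co-assignment posterior (Bayes rule over the five
components) makes the normalization pool stimulus dependent: a surround group
divides the center response only to the extent that the stimulus statistics
say center and surround belong to one visual structure. Even/odd phase
estimates are combined as a root sum of squares into orientation-tuned,
phase-invariant responses.

## Filter bank

Each RF is a Gabor quadrature pair windowed to a 9-px circular disc,
zero-mean and unit L2 norm, at 4 orientations (0, 45, 90, 135 deg from
vertical). Three kernel parameters are calibrated at build time against
measurements on the final windowed kernels:

* carrier frequency, so the measured peak spatial frequency is exactly
  `1/6` cyc/px (calibrated value 0.1669 cyc/px);
* envelope sigma along the bar axis (2.38 px), so the orientation tuning of
  the quadrature energy has a 23.5-deg half-width at 70% of peak — the median
  V1 bandwidth this model family is built to match. A fixed steerable-pyramid
  derivative kernel was considered instead, but its angular tuning is fixed
  by the orientation count (about 27 deg half-width for four orientations)
  and cannot meet the bandwidth target, so the calibrated Gabor pair is used;
* envelope sigma along the wave axis (2.96 px), so the even and odd kernels
  respond to the peak grating with equal amplitude. Truncation and DC removal
  otherwise unbalance the pair; with the calibration, quadrature energy is
  phase invariant to ~1e-11 at the preferred orientation and < 1% at 45 deg
  (raster sampling).

Kernels at orientation theta + 90 are exact `rot90` copies of those at
theta, and the surround offsets are integer pixel positions, so projecting a
90-deg-rotated image yields exactly permuted outputs. The diagonal surround
positions round to offsets (+-4, +-4) (radius 5.66 rather than 6): exact
rotation symmetry on the raster was preferred over exact radius. The
45-deg layout rotation acts on the filter index set as a *signed*
permutation — odd-phase filters flip sign when their orientation wraps past
180 deg — which is what covariance renormalization and the equivariance
tests use.

The patch is 23 x 23 px (surround offset 6 + kernel radius 4 leaves a 1-px
margin); projection outside the image raises an error rather than padding.

## Training

Parameters (nine covariances and five priors) are fit by generalized EM: each
sub-cycle runs a full E-step (component responsibilities) and a partial
M-step on one covariance, by conjugate gradients in a Cholesky
parameterization with log-transformed diagonal (every iterate is positive
definite by construction). Because each covariance enters the complete-data
likelihood only through responsibility-weighted GSM factors, each partial
M-step is a weighted GSM maximum-likelihood problem; its analytic gradient
uses the Bessel recurrence `K_{a+1} = K_{a-1} + (2a/lambda) K_a`. Priors are
the closed-form responsibility means. A CG update is kept only if it does not
decrease its objective, so the marginal log-likelihood is non-decreasing
across cycles (asserted in tests). Defaults: relative log-likelihood
tolerance 1e-6, at most 200 cycles, 10-20 CG iterations per partial step,
moment initialization (sample covariance blocks scaled by 1/E[nu^2] = 1/2,
plus 1e-3 identity jitter); restarts perturb the initialization diagonally.
Patches are mean-subtracted before projection; no whitening.

After fitting, `renormalize_rotational` averages the covariances over the
order-8 layout-rotation group (45-deg steps; the steps beyond 180/n_or map
each orientation group to itself with a half-turn position shift and
odd-phase sign flips). Afterwards the joint covariances are exact rotated
copies of one template, the center covariance is rotation invariant, and the
co-assigned priors are equal, which guarantees that responses to rotated
stimuli are exactly permuted copies. The center covariance and priors are
included in the averaging — without them the guarantee would not hold
exactly. The operation is idempotent.

## Synthetic data

Two generators define the study conditions; no external images are required.

**Ground-truth parameters** (`structured_params`). A 24 x 24 template for the
vertical co-assigned component encodes the covariance structure this model
family attributes to natural scenes: boosted variance for the center filters
at the component's orientation (base variance 0.008, boost x3.5); surround
per-filter variance a quarter of the center's (an oriented contour through
the center crosses the ring only at the collinear positions), with a 1.5x
boost at those positions; center-surround correlation falling from 0.3
(collinear) to 0.05 (parallel) as cos^2 of position angle, same-phase terms
only; 0.1 correlation between neighboring ring positions. The other
components are exact rotated copies (the set is a fixed point of
renormalization). The independent component reuses the same template: each
`C_s[g]` is the surround block of `C_cs[g]`, and `C_c` keeps the co-assigned
(boosted) variance scale with the averaged center correlations, so estimates
do not jump when a stimulus recruits the surround. The prior of the
independent configuration is 0.6. With these values the model expresses the
full qualitative battery: contrast-dependent receptive-field expansion,
iso-orientation-maximal surround suppression with near-none orthogonally,
suppression tracking the stimulus rather than the preferred orientation,
tuning narrowing, collinear/parallel positional asymmetry with low-contrast
facilitation, orientation pop-out with saturation, and collinear border
enhancement. The parameter-recovery acceptance check fits 25,000 samples of
this model from scratch and recovers priors within 0.05 and every covariance
within 10% relative Frobenius error; the experiment battery then runs on the
*recovered* (not the ground-truth) parameters.

**Pseudo-natural images** (`pseudo_natural_image`). Long, thin anti-aliased
strokes (half aligned near the cardinal axes, as in scenes), large smooth
luminance blobs and low-amplitude smoothed noise, under a slowly varying
contrast envelope, at RMS contrast 0.25. Filter outputs on these images show
the dependency signature the model feeds on: strong bowtie variance
dependence, collinear linear correlation ~0.5 at one RF spacing, near-zero
parallel correlation. They lack occlusion, shading and multi-scale texture.
Unsupervised fits on this ensemble learn the qualitative covariance
signature (collinear surround variance and center-collinear covariance above
their parallel counterparts) and a monotone contrast dependence of surround
recruitment, but they split the mixture by overall activity — the
independent component captures low-contrast patches, so its covariances come
out far smaller than the co-assigned blocks — and therefore do not reproduce
the full response battery. This is a property of maximum likelihood for this
mixture on ensembles whose activity is spatially clustered, not a training
defect: fits on model-consistent samples recover their generator. The
battery is accordingly tied to the MGSM-sampled fixture, and passing it
demonstrates that inference plus the experiment protocols produce the
published phenomenology for covariances with the documented natural-scene
structure, not that any image ensemble trains to that structure.

## Experiment protocols (defaults)

All stimuli are generated at the filter peak spatial frequency with
hard-edged apertures on 23-px patches; gray = 0, gratings use Michelson
contrast, noise RMS contrast. "Full surround extent" is a 21-px outer
diameter; annuli leave an 11-px inner diameter so they never encroach on the
9-px center RF. Values the source experiments leave open are fixed here as:
size-tuning contrasts (0.12, 0.8); "mid" contrast 0.5 for annulus protocols;
positional-bias sectors between diameters 11 and 21 with the same contrast on
center and sectors; flankers as collinear 60-deg sectors at contrasts
0.5-0.8; bars 5 px long, 1 px wide, 6-px spacing (equal to the RF spacing),
drawn with a Gaussian cross-section so oblique bars are as smooth as cardinal
ones; salience sampled every 6 px; pop-out displays are 7 x 7 arrays with a
fixed vertical target and tilted distractors, and the pop-out comparison uses
interior bar locations (the outermost ring of a finite display has genuinely
reduced surround suppression — a border effect — that would confound it).
Tuning-narrowing compares a 7-px with a 21-px grating at 70% height: the
small stimulus must stay clear of the surround RFs or its own curve is
already narrowed by encroachment-driven co-assignment.

## Numerical choices

* `epsilon = 1e-10` inside every `lambda` (a gain floor for zero input);
  configurable.
* Bessel functions are evaluated in exponentially scaled form; below
  `lambda = 1e-6` a small-argument series replaces them.
* Log-domain likelihoods with log-sum-exp throughout (24-dim Gaussians
  underflow otherwise).
* Size-tuning peaks are the argmax over the sampled diameter grid; half-widths
  interpolate linearly between samples and average the two flanks.
* Serialization: JSON metadata + NPZ arrays, bit-exact round trip, SHA-256
  content hash.

## Problem sizes

The test suite trains twice: one GEM fit on 25,000 MGSM-sampled vectors
(about 25 cycles to convergence; this single run backs both the recovery
check and the experiment battery) and one smoke fit on 5,000 pseudo-natural
patches (12 cycles). Examples use smaller runs. The per-image training loop
of the source study (dozens of photographs, three restarts each) is supported
by the API (`gem_fit` with `n_restarts`, per-image calls) but not exercised.

## Known limitations

* Trained on synthetic ensembles, the mixture splits by overall contrast (see
  above); published magnitudes that depend on photographic training images —
  16% peak flanker facilitation at 0.2 center contrast, 1-6% suppression at
  high contrast, 0.51 background relative pop-out salience — are not
  reproduced at their printed values, and the corresponding acceptance test
  documents this as an expected failure. The size-tuning expansion factor
  (>= 2.3) is reproduced.
* In the low-activity regime the mixture's co-assignment posterior is driven
  by dimension-counting prefactors rather than structure; with very weak
  stimuli this can transiently favor co-assignment (visible as a small bump
  at the co-assignment boundary in low-contrast size-tuning curves).
* Only the Rayleigh mixer prior is implemented; only expected values (not
  full posteriors) of the Gaussian variables are computed; there is no
  recurrent or temporal processing, no learned filter shapes, and the
  surround grouping (one group per orientation across all positions) is
  fixed.
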