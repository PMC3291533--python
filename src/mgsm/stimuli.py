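"""Synthetic stimuli and natural-image patch sampling.

All stimuli are grayscale arrays with gray = 0 and pixel values nominally in
[-1, 1]; luminance is ``(1 + pixels) / 2``.  Gratings use Michelson contrast
(equal to the sinusoid amplitude under this convention), noise and natural
patches use RMS contrast (the pixel standard deviation).  Apertures are
hard-edged: gap and encroachment effects on the surround receptive fields
depend on them.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .geometry import (angular_distance, disc_mask, oriented_axes,
                       position_angle, radial_distance)


class StimulusError(ValueError):
    pass


@dataclass
class StimulusImage:
    pixels: np.ndarray
    contrast: float
    kind: str = "custom"
    meta: dict = dfield(default_factory=dict)

    @property
    def shape(self):
        return self.pixels.shape

    @property
    def mask(self):
        return self.meta.get("mask")

    def save_png(self, path):
        import imageio.v3 as iio

        arr = np.clip((self.pixels + 1.0) * 127.5, 0, 255).astype(np.uint8)
        iio.imwrite(path, arr)


def _validate(contrast, image_size):
    if not 0.0 <= contrast <= 1.0:
        raise StimulusError(f"contrast must be in [0, 1], got {contrast}")
    if image_size <= 0:
        raise StimulusError("image_size must be positive")


def _windowed_grating(mask, contrast, orientation, sf, phase_deg, image_size,
                      kind, **meta):
    u, _ = oriented_axes((image_size, image_size), orientation)
    pix = contrast * np.cos(2 * np.pi * sf * u + np.deg2rad(phase_deg)) * mask
    return StimulusImage(pix, contrast, kind,
                         {"mask": mask, "orientation": orientation, "sf": sf,
                          "phase": phase_deg, **meta})


def grating(diameter, contrast, orientation=0.0, sf=1.0 / 6.0, phase=0.0,
            image_size=23) -> StimulusImage:
    """Sinusoidal grating in a hard circular window, gray outside."""
    if diameter < 0:
        raise StimulusError("diameter must be nonnegative")
    _validate(contrast, image_size)
    mask = disc_mask((image_size, image_size), diameter)
    return _windowed_grating(mask, contrast, orientation, sf, phase,
                             image_size, "grating", diameter=diameter)


def annulus(inner_diameter, outer_diameter, contrast, orientation=0.0,
            sf=1.0 / 6.0, phase=0.0, image_size=23) -> StimulusImage:
    """Grating restricted to an annular ring (inner < d <= outer)."""
    if inner_diameter > outer_diameter:
        raise StimulusError("inner_diameter must not exceed outer_diameter")
    _validate(contrast, image_size)
    d = 2.0 * radial_distance((image_size, image_size))
    mask = (d > inner_diameter) & (d <= outer_diameter)
    return _windowed_grating(mask, contrast, orientation, sf, phase,
                             image_size, "annulus",
                             inner_diameter=inner_diameter,
                             outer_diameter=outer_diameter)


def annular_sector(inner_diameter, outer_diameter, angular_center,
                   angular_size, contrast, orientation=0.0, sf=1.0 / 6.0,
                   phase=0.0, image_size=23) -> StimulusImage:
    """Grating restricted to two opposed sectors of an annulus.

    ``angular_center`` is the position angle (deg CCW from vertical) of one
    sector; the mirror sector at +180 deg is included as well, matching the
    two-patch surround configurations used for positional-bias protocols.
    ``angular_size`` = 360 recovers the full annulus.
    """
    if not 0 < angular_size <= 360:
        raise StimulusError("angular_size must be in (0, 360]")
    if inner_diameter > outer_diameter:
        raise StimulusError("inner_diameter must not exceed outer_diameter")
    _validate(contrast, image_size)
    d = 2.0 * radial_distance((image_size, image_size))
    ring = (d > inner_diameter) & (d <= outer_diameter)
    pa = position_angle((image_size, image_size))
    ang = np.minimum(angular_distance(pa, angular_center),
                     angular_distance(pa, angular_center + 180.0))
    mask = ring & (ang <= angular_size / 2.0)
    return _windowed_grating(mask, contrast, orientation, sf, phase,
                             image_size, "annular_sector",
                             inner_diameter=inner_diameter,
                             outer_diameter=outer_diameter,
                             angular_center=angular_center,
                             angular_size=angular_size)


def compose(*stimuli: StimulusImage) -> StimulusImage:
    """Pixelwise sum of stimuli with disjoint supports.

    Raises :class:`StimulusError` if any two supports overlap (the sum would
    clip or superpose, which the protocols here never intend).
    """
    if not stimuli:
        raise StimulusError("nothing to compose")
    shape = stimuli[0].shape
    total = np.zeros(shape)
    cover = np.zeros(shape, dtype=int)
    for s in stimuli:
        if s.shape != shape:
            raise StimulusError("stimuli must share the same shape")
        m = s.mask if s.mask is not None else (s.pixels != 0)
        cover += m.astype(int)
        total += s.pixels
    if (cover > 1).any():
        raise StimulusError("stimulus supports overlap; composition refused")
    return StimulusImage(total, max(s.contrast for s in stimuli), "composite",
                         {"mask": cover > 0,
                          "parts": [s.kind for s in stimuli]})


def bar_array(orientation_map, bar_length=5, bar_width=1, spacing=6,
              contrast=1.0, image_size=None, margin=11) -> StimulusImage:
    """Array of bright oriented bars on gray.

    ``orientation_map`` is a 2-D array of bar orientations in degrees; NaN
    cells stay empty.  Cell (i, j) is centered at ``(margin + i * spacing,
    margin + j * spacing)``.  Bars are thin anti-aliased strokes
    ``bar_length`` pixels long with peak luminance ``contrast`` above gray
    (a Gaussian cross-section, so oblique bars are as smooth as cardinal
    ones).  Overlapping bars raise a layout error.
    """
    if spacing < 1:
        raise StimulusError("spacing must be >= 1")
    omap = np.atleast_2d(np.asarray(orientation_map, dtype=float))
    nr, nc = omap.shape
    if image_size is None:
        image_size = 2 * margin + spacing * (max(nr, nc) - 1) + 1
    pix = np.zeros((image_size, image_size))
    owner = -np.ones((image_size, image_size), dtype=int)
    centers = np.full((nr, nc, 2), -1, dtype=int)
    sigma = max(bar_width / 2.0, 0.5)
    half = bar_length / 2.0
    rr, cc = np.mgrid[:image_size, :image_size].astype(float)
    for i in range(nr):
        for j in range(nc):
            th = omap[i, j]
            if np.isnan(th):
                continue
            r0, c0 = margin + i * spacing, margin + j * spacing
            centers[i, j] = (r0, c0)
            a = np.deg2rad(th)
            dirv = np.array([-np.cos(a), -np.sin(a)])   # along the bar, "up" at 0
            pad = int(np.ceil(half + 3 * sigma)) + 1
            lo_r, hi_r = r0 - pad, r0 + pad + 1
            lo_c, hi_c = c0 - pad, c0 + pad + 1
            if lo_r < 0 or lo_c < 0 or hi_r > image_size or hi_c > image_size:
                raise StimulusError("bar falls outside the image")
            R = rr[lo_r:hi_r, lo_c:hi_c] - r0
            C = cc[lo_r:hi_r, lo_c:hi_c] - c0
            t = R * dirv[0] + C * dirv[1]
            s = R * (-dirv[1]) + C * dirv[0]
            stroke = contrast * np.exp(-s**2 / (2 * sigma**2))
            stroke *= np.clip(half + 0.5 - np.abs(t), 0.0, 1.0)
            lit = stroke > 0.05 * contrast
            cell = i * nc + j
            region_owner = owner[lo_r:hi_r, lo_c:hi_c]
            clash = lit & (region_owner != -1) & (region_owner != cell)
            if clash.any():
                raise StimulusError(
                    f"bars of cells {divmod(int(region_owner[clash][0]), nc)} "
                    f"and {(i, j)} overlap")
            region_owner[lit] = cell
            pix[lo_r:hi_r, lo_c:hi_c] += stroke
    return StimulusImage(pix, contrast, "bar_array",
                         {"mask": owner >= 0, "spacing": spacing,
                          "margin": margin, "bar_length": bar_length,
                          "centers": centers, "orientation_map": omap})


def white_noise(size, rms_contrast, seed=0) -> StimulusImage:
    """Gaussian white noise with the stated RMS contrast (in expectation)."""
    if rms_contrast < 0:
        raise StimulusError("rms_contrast must be nonnegative")
    rng = np.random.default_rng(seed)
    pix = rng.normal(0.0, rms_contrast, size=(size, size))
    return StimulusImage(pix, rms_contrast, "white_noise", {"seed": seed})


def sample_patches(images, n, patch_size, seed=0) -> np.ndarray:
    """Sample ``n`` square patches uniformly at random from a set of images.

    Positions are drawn with a seeded generator, cycling through the images,
    so the same seed always yields the same patch set.  Returns an
    (n, patch_size, patch_size) array.
    """
    if n < 1:
        raise StimulusError("n must be >= 1")
    arrays = [np.asarray(getattr(im, "pixels", im), dtype=float)
              for im in images]
    for a in arrays:
        if a.shape[0] < patch_size or a.shape[1] < patch_size:
            raise StimulusError(
                f"patch_size {patch_size} exceeds source image {a.shape}")
    rng = np.random.default_rng(seed)
    out = np.empty((n, patch_size, patch_size))
    which = rng.integers(0, len(arrays), size=n)
    for i in range(n):
        a = arrays[which[i]]
        r = rng.integers(0, a.shape[0] - patch_size + 1)
        c = rng.integers(0, a.shape[1] - patch_size + 1)
        out[i] = a[r:r + patch_size, c:c + patch_size]
    return out
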