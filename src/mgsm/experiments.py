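"""Simulated neurophysiology and perceptual-salience protocols.

Every protocol builds synthetic stimuli, projects them onto the filter bank
at the patch center (or a sampling grid for salience maps), computes model
responses and returns a tidy table plus a summary of the derived quantities
(peak diameters, half-widths, suppression ratios, enhancements, ...).  All
protocols are deterministic given the parameters and their configuration.

Unless stated otherwise the conventions follow the package defaults: the
reported unit is the vertical center orientation; gratings are at the filter
peak spatial frequency; "mid" contrast is 0.5; the outer diameter that covers
the full surround extent is 21 px (surround offset 6 + kernel radius 4.5,
times two); annuli leave an 11-px inner diameter so that the surround
stimulus never encroaches on the 9-px center RF.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MGSMParams
from .filterbank import FilterBank, project, project_patches
from .inference import respond, respond_batch
from .io import params_hash
from .stimuli import StimulusImage, annular_sector, annulus, bar_array, compose, grating

FULL_SURROUND_DIAMETER = 21
ANNULUS_INNER = 11
MID_CONTRAST = 0.5


@dataclass
class ExperimentResult:
    table: pd.DataFrame
    summary: dict
    extras: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


@dataclass
class SalienceMap:
    """Per-location salience: max over the orientation-tuned responses."""

    salience: np.ndarray   # (n_rows, n_cols)
    rows: np.ndarray       # image row of each map row
    cols: np.ndarray       # image col of each map col

    def argmax_location(self):
        i, j = np.unravel_index(int(np.argmax(self.salience)),
                                self.salience.shape)
        return int(self.rows[i]), int(self.cols[j])


def _meta(params, **kw):
    return {"params_hash": params_hash(params), **kw}


def _respond_center(stim: StimulusImage, bank: FilterBank, params: MGSMParams):
    return respond(project(stim, bank), params)


def reduced_model(params: MGSMParams, mode: str) -> MGSMParams:
    """Ablated parameter sets used as controls.

    ``fixed_assignment`` always normalizes the center by the vertical
    surround group (the co-assignment posterior is bypassed);
    ``diagonal_covariance`` keeps the learned variances but zeroes all
    off-diagonal covariance terms; ``isotropic_covariance`` additionally
    equalizes the variances (each matrix becomes proportional to the
    identity), removing every spatial anisotropy the model learned.
    """
    if mode == "fixed_assignment":
        return params.copy(forced_component=1)
    if mode == "diagonal_covariance":
        return params.copy(
            C_c=np.diag(np.diag(params.C_c)),
            C_s=np.stack([np.diag(np.diag(C)) for C in params.C_s]),
            C_cs=np.stack([np.diag(np.diag(C)) for C in params.C_cs]))
    if mode == "isotropic_covariance":
        def iso(C):
            return np.mean(np.diag(C)) * np.eye(C.shape[0])
        return params.copy(
            C_c=iso(params.C_c),
            C_s=np.stack([iso(C) for C in params.C_s]),
            C_cs=np.stack([iso(C) for C in params.C_cs]))
    raise ValueError(f"unknown reduced mode {mode!r}")


# --- grating protocols ------------------------------------------------------

def size_tuning(bank, params, contrasts=(0.12, 0.8),
                diameters=tuple(range(1, 24, 2)), orientation=0.0,
                sf=None) -> ExperimentResult:
    """Response and co-assignment vs grating diameter at several contrasts.

    Summarizes the peak-response diameter per contrast and the expansion
    factor, peak diameter at the lowest contrast over the highest.
    """
    if len(contrasts) < 2:
        raise ValueError("need at least two contrasts")
    sf = sf if sf is not None else bank.spec.peak_sf
    size = bank.spec.patch_size
    rows = []
    for c in contrasts:
        for d in diameters:
            r = _respond_center(grating(d, c, orientation, sf, image_size=size),
                                bank, params)
            rows.append({"contrast": c, "diameter": d,
                         "response": r.response[0],
                         "p_coassign_vertical": r.posterior[1],
                         "p_independent": r.posterior[0]})
    df = pd.DataFrame(rows)
    peaks = {c: int(g.loc[g.response.idxmax(), "diameter"])
             for c, g in df.groupby("contrast")}
    c_lo, c_hi = min(contrasts), max(contrasts)
    summary = {"peak_diameter": peaks,
               "expansion_factor": peaks[c_lo] / peaks[c_hi]}
    return ExperimentResult(df, summary, meta=_meta(params, sf=sf))


def surround_orientation_tuning(bank, params, center_diameter=9,
                                center_orientation=0.0,
                                annulus_inner=ANNULUS_INNER,
                                annulus_outer=FULL_SURROUND_DIAMETER,
                                surround_orientations=tuple(range(0, 181, 15)),
                                contrast=MID_CONTRAST,
                                unit_orientation_index=0) -> ExperimentResult:
    """Modulation of a fixed center grating by an annulus of varying orientation.

    The reported unit is given by ``unit_orientation_index`` (vertical by
    default) even when the center stimulus is tilted away from it, which is
    how surround tuning for non-optimal center stimuli is probed.
    """
    size = bank.spec.patch_size
    center = grating(center_diameter, contrast, center_orientation,
                     bank.spec.peak_sf, image_size=size)
    r0 = _respond_center(center, bank, params)
    rows = []
    for so in surround_orientations:
        ann = annulus(annulus_inner, annulus_outer, contrast, so,
                      bank.spec.peak_sf, image_size=size)
        r = _respond_center(compose(center, ann), bank, params)
        row = {"surround_orientation": so,
               "orientation_difference": abs(
                   (so - center_orientation + 90) % 180 - 90),
               "response": r.response[unit_orientation_index]}
        for j, p in enumerate(r.posterior):
            row[f"p_component_{j}"] = p
        rows.append(row)
    summary = {"center_alone_response": r0.response[unit_orientation_index],
               "center_orientation": center_orientation}
    return ExperimentResult(pd.DataFrame(rows), summary,
                            meta=_meta(params, contrast=contrast,
                                       center_diameter=center_diameter))


def tuning_narrowing(bank, params, small_diameter=7,
                     large_diameter=FULL_SURROUND_DIAMETER,
                     orientations=tuple(range(-90, 91, 5)),
                     contrast=MID_CONTRAST, height=0.7) -> ExperimentResult:
    """Orientation tuning of the vertical unit with small vs large gratings.

    Large gratings recruit the co-assigned surround, which suppresses
    responses at non-optimal orientations more than at the peak, narrowing
    the normalized tuning curve.
    """
    size = bank.spec.patch_size
    rows = []
    for label, d in (("small", small_diameter), ("large", large_diameter)):
        for o in orientations:
            r = _respond_center(grating(d, contrast, o, bank.spec.peak_sf,
                                        image_size=size), bank, params)
            rows.append({"size": label, "diameter": d, "orientation": o,
                         "response": r.response[0]})
    df = pd.DataFrame(rows)
    summary = {"halfwidth_height": height}
    for label, g in df.groupby("size"):
        g = g.sort_values("orientation")
        resp = g.response.to_numpy()
        ori = g.orientation.to_numpy()
        peak = resp.max()
        norm = resp / peak
        summary[f"halfwidth_{label}"] = _halfwidth(ori, norm, height)
        summary[f"peak_orientation_{label}"] = float(ori[int(np.argmax(resp))])
    return ExperimentResult(df, summary, meta=_meta(params, contrast=contrast))


def _halfwidth(ori, norm_resp, height):
    """Half-width of a normalized tuning curve, averaged over both flanks."""
    i0 = int(np.argmax(norm_resp))
    widths = []
    for sl in (slice(i0, None, 1), slice(i0, None, -1)):
        o, r = ori[sl], norm_resp[sl]
        below = np.nonzero(r < height)[0]
        if below.size:
            i = below[0]
            w = abs(o[i - 1] - o[0]) + (r[i - 1] - height) / (r[i - 1] - r[i]) \
                * abs(o[i] - o[i - 1])
            widths.append(w)
    if not widths:
        return np.nan
    return float(np.mean(widths))


# --- positional bias and flankers ------------------------------------------

def _sector_stimulus(bank, center_contrast, sector_contrast, angular_center,
                     angular_size, sector_orientation, center_diameter=9,
                     inner=ANNULUS_INNER, outer=FULL_SURROUND_DIAMETER):
    size = bank.spec.patch_size
    parts = []
    if center_contrast > 0:
        parts.append(grating(center_diameter, center_contrast, 0.0,
                             bank.spec.peak_sf, image_size=size))
    if sector_contrast > 0 and angular_size > 0:
        parts.append(annular_sector(inner, outer, angular_center, angular_size,
                                    sector_contrast, sector_orientation,
                                    bank.spec.peak_sf, image_size=size))
    if not parts:
        parts.append(grating(center_diameter, 0.0, 0.0, bank.spec.peak_sf,
                             image_size=size))
    return compose(*parts) if len(parts) > 1 else parts[0]


def positional_bias(bank, params, arrangements=("collinear", "parallel"),
                    surround_orientation="iso",
                    contrasts=tuple(np.round(np.linspace(0.05, 0.95, 10), 3)),
                    angular_sizes=tuple(range(15, 181, 15)),
                    center_diameter=9, polar_angular_size=60,
                    polar_contrast=MID_CONTRAST) -> ExperimentResult:
    """Suppression-ratio grids for sector surrounds at the RF ends vs sides.

    For a vertical center grating, "collinear" sectors sit at the ends of the
    RF (position angles 0/180 deg) and "parallel" sectors at its sides
    (90/270 deg).  ``surround_orientation`` is "iso" (sectors share the
    center orientation) or "orthogonal".  The same contrast drives center and
    sectors.  The summary carries the collinear-minus-parallel difference
    grid; the extras a polar sweep of the sector position at fixed size.
    """
    sector_ori = 0.0 if surround_orientation == "iso" else 90.0
    angle_of = {"collinear": 0.0, "parallel": 90.0}
    rows = []
    for arr in arrangements:
        for c in contrasts:
            center_alone = _respond_center(
                _sector_stimulus(bank, c, 0.0, 0.0, 0.0, sector_ori,
                                 center_diameter), bank, params)
            for a in angular_sizes:
                r = _respond_center(
                    _sector_stimulus(bank, c, c, angle_of[arr], a, sector_ori,
                                     center_diameter), bank, params)
                rows.append({
                    "arrangement": arr, "contrast": c, "angular_size": a,
                    "response": r.response[0],
                    "center_alone": center_alone.response[0],
                    "suppression_ratio": r.response[0] / center_alone.response[0],
                    "p_coassign_vertical": r.posterior[1]})
    df = pd.DataFrame(rows)
    extras = {}
    if set(arrangements) >= {"collinear", "parallel"}:
        grids = {arr: g.pivot(index="contrast", columns="angular_size",
                              values="suppression_ratio")
                 for arr, g in df.groupby("arrangement")}
        extras["difference_grid"] = grids["collinear"] - grids["parallel"]
        extras["suppression_grids"] = grids

    # polar map: sector position swept around the circle at fixed size
    polar_rows = []
    c = polar_contrast
    center_alone = _respond_center(
        _sector_stimulus(bank, c, 0.0, 0.0, 0.0, sector_ori, center_diameter),
        bank, params)
    for ang in range(0, 360, 45):
        r = _respond_center(
            _sector_stimulus(bank, c, c, ang, polar_angular_size, sector_ori,
                             center_diameter), bank, params)
        polar_rows.append({"position_angle": ang, "response": r.response[0],
                           "suppression_ratio":
                               r.response[0] / center_alone.response[0],
                           "p_coassign_vertical": r.posterior[1]})
    extras["polar"] = pd.DataFrame(polar_rows)
    summary = {"surround_orientation": surround_orientation,
               "polar_center_alone": center_alone.response[0]}
    return ExperimentResult(df, summary, extras,
                            meta=_meta(params, center_diameter=center_diameter))


def suppression_vector(polar_table: pd.DataFrame):
    """Angle and magnitude of maximal suppression from a polar sweep.

    The response reduction at each sector position is treated as a vector
    (duplicated around the circle because position is defined modulo 180 for
    an orientation axis); the resultant's angle locates the most suppressive
    surround region, its normalized magnitude the orientation bias.
    """
    red = np.maximum(1.0 - polar_table.suppression_ratio.to_numpy(), 0.0)
    ang = np.deg2rad(2.0 * polar_table.position_angle.to_numpy())
    vec = (red * np.exp(1j * ang)).sum()
    bias = np.abs(vec) / max(red.sum(), 1e-12)
    return {"angle": float(np.degrees(np.angle(vec)) / 2.0 % 180.0),
            "orientation_bias": float(bias),
            "max_suppression": float(red.max())}


def flanker_modulation(bank, params,
                       center_contrasts=(0.1, 0.2, 0.35, 0.5, 0.65, 0.8),
                       flanker_contrasts=(0.5, 0.65, 0.8),
                       angular_size=60, center_diameter=9) -> ExperimentResult:
    """Percent modulation by collinear flankers vs center contrast.

    Flankers are collinear iso-oriented sectors at fixed (high) contrasts;
    the modulation for each center contrast is averaged over the flanker
    contrast range.  Weakly driven centers are facilitated, strongly driven
    ones weakly suppressed.
    """
    rows = []
    for cc in center_contrasts:
        r0 = _respond_center(
            _sector_stimulus(bank, cc, 0.0, 0.0, 0.0, 0.0, center_diameter),
            bank, params)
        for fc in flanker_contrasts:
            r = _respond_center(
                _sector_stimulus(bank, cc, fc, 0.0, angular_size, 0.0,
                                 center_diameter), bank, params)
            rows.append({"center_contrast": cc, "flanker_contrast": fc,
                         "modulation_percent":
                             100.0 * (r.response[0] - r0.response[0])
                             / r0.response[0]})
    df = pd.DataFrame(rows)
    mean_mod = df.groupby("center_contrast").modulation_percent.mean()
    summary = {"mean_modulation": mean_mod.to_dict(),
               "peak_facilitation": float(mean_mod.max()),
               "peak_facilitation_contrast": float(mean_mod.idxmax())}
    return ExperimentResult(df, summary, meta=_meta(params))


# --- salience ---------------------------------------------------------------

def salience_map(stim: StimulusImage, bank, params,
                 grid_spacing=6, origin=None) -> SalienceMap:
    """Max-over-orientations model response on a grid of image locations."""
    pixels = stim.pixels
    h, w = pixels.shape
    p = bank.spec.patch_size
    margin = max(bank.footprint_radius(), (p - 1) // 2)
    if origin is None:
        origin = (margin, margin)
    half = (p - 1) // 2
    rows = np.arange(origin[0], h - half, grid_spacing, dtype=int)
    cols = np.arange(origin[1], w - half, grid_spacing, dtype=int)
    if rows.size == 0 or cols.size == 0:
        raise ValueError("no grid location has a full filter footprint inside "
                         "the image")
    patches = np.stack([pixels[r - half: r + half + 1, c - half: c + half + 1]
                        for r in rows for c in cols])
    X = project_patches(patches, bank)
    resp = respond_batch(X, params)
    sal = resp.max(axis=1).reshape(len(rows), len(cols))
    return SalienceMap(sal, rows, cols)


def popout_curve(bank, params, orientation_contrasts=(0, 15, 30, 45, 60, 75, 90),
                 n_rows=7, n_cols=7, bar_length=5, spacing=6, contrast=1.0,
                 target_orientation=0.0) -> ExperimentResult:
    """Salience of an orientation-contrast target in a homogeneous bar array.

    A fixed central target bar is embedded in a background of distractor bars
    tilted away from it by the stated orientation contrast.  Target saliences
    are rescaled to a maximum of 1; the background's relative salience (mean
    over non-target interior bars of the homogeneous array, same scale) is
    reported alongside.  The pop-out check ("is_argmax") compares the target
    against the other interior bar locations; the outermost ring of bars has
    genuinely reduced surround suppression (a border effect) and would
    confound the orientation-contrast comparison in a finite display.
    """
    margin = bank.footprint_radius() + 1
    rows = []
    maps = {}
    ti, tj = n_rows // 2, n_cols // 2
    for dori in orientation_contrasts:
        omap = np.full((n_rows, n_cols), target_orientation + dori)
        omap[ti, tj] = target_orientation
        stim = bar_array(omap, bar_length=bar_length, spacing=spacing,
                         contrast=contrast, margin=margin)
        smap = salience_map(stim, bank, params, grid_spacing=spacing,
                            origin=(margin, margin))
        target = smap.salience[ti, tj]
        interior = smap.salience[1:-1, 1:-1]
        bg_mask = np.ones_like(interior, dtype=bool)
        bg_mask[ti - 1, tj - 1] = False
        rows.append({"orientation_contrast": dori, "target_salience": target,
                     "background_salience": interior[bg_mask].mean(),
                     "is_argmax": bool(interior.max() == target)})
        maps[dori] = smap
    df = pd.DataFrame(rows)
    scale = df.target_salience.max()
    df["target_rescaled"] = df.target_salience / scale
    homog_bg = float(df.loc[df.orientation_contrast == 0,
                            "background_salience"].iloc[0]) \
        if (df.orientation_contrast == 0).any() else float(df.background_salience.min())
    summary = {"background_relative_salience": homog_bg / scale}
    return ExperimentResult(df, summary, extras={"maps": maps},
                            meta=_meta(params, contrast=contrast,
                                       bar_length=bar_length, spacing=spacing))


def _texture_with_middle_row(n_rows, n_cols, field_ori, middle_ori):
    omap = np.full((n_rows, n_cols), float(field_ori))
    omap[n_rows // 2, :] = float(middle_ori)
    return omap


def border_enhancement(bank, params, variant="collinear_row", n_rows=9,
                       n_cols=9, bar_length=5, spacing=6,
                       contrast=1.0) -> ExperimentResult:
    """Salience enhancement at texture rows/borders of oriented bar arrays.

    Variants:
      * ``collinear_row``: vertical-bar texture with a middle row of
        horizontal bars; the middle row is a collinear arrangement (Col), its
        neighbors parallel (Par).
      * ``parallel_row``: horizontal-bar texture with a middle row of
        vertical bars; the middle row is the parallel arrangement, its
        neighbors collinear.
      * ``border``: top half vertical, bottom half horizontal; the horizontal
        row adjacent to the border is Col, the vertical row Par.

    Enhancement is (mean salience of labeled bars - Txt) / Txt, with Txt the
    mean over bars deep inside homogeneous texture (enhancement 0 by
    definition).
    """
    mid = n_rows // 2
    if variant == "collinear_row":
        omap = _texture_with_middle_row(n_rows, n_cols, 0.0, 90.0)
        labels = {"col": [mid], "par": [mid - 1, mid + 1],
                  "txt": [0, 1, n_rows - 2, n_rows - 1]}
    elif variant == "parallel_row":
        omap = _texture_with_middle_row(n_rows, n_cols, 90.0, 0.0)
        labels = {"par": [mid], "col": [mid - 1, mid + 1],
                  "txt": [0, 1, n_rows - 2, n_rows - 1]}
    elif variant == "border":
        omap = np.full((n_rows, n_cols), 0.0)
        omap[mid:, :] = 90.0
        labels = {"par": [mid - 1], "col": [mid],
                  "txt": [0, 1, n_rows - 2, n_rows - 1]}
    else:
        raise ValueError(f"unknown variant {variant!r}")
    margin = bank.footprint_radius() + 1
    stim = bar_array(omap, bar_length=bar_length, spacing=spacing,
                     contrast=contrast, margin=margin)
    smap = salience_map(stim, bank, params, grid_spacing=spacing,
                        origin=(margin, margin))
    # salience rows align with bar rows by construction
    interior = slice(1, n_cols - 1)   # avoid lateral edge effects
    mean_by_row = smap.salience[:, interior].mean(axis=1)
    means = {lab: float(np.mean([mean_by_row[i] for i in idx]))
             for lab, idx in labels.items()}
    txt = means["txt"]
    rows = [{"label": lab, "mean_salience": m,
             "enhancement": (m - txt) / txt} for lab, m in means.items()]
    summary = {"col_enhancement": (means["col"] - txt) / txt,
               "par_enhancement": (means["par"] - txt) / txt,
               "txt_enhancement": 0.0,
               "variant": variant}
    return ExperimentResult(pd.DataFrame(rows), summary,
                            extras={"map": smap, "row_means": mean_by_row},
                            meta=_meta(params, variant=variant))
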