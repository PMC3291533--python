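"""Shared raster-geometry conventions.

Coordinates are (row, col) with row increasing downward.  Angles (both filter
orientation and angular position on the surround circle) are measured in
degrees counterclockwise from vertical as seen on screen, i.e. 0 deg points
"up", 90 deg points "left".  Orientations are defined modulo 180, positions
modulo 360.
"""
from __future__ import annotations

import numpy as np


def oriented_axes(shape, orientation_deg, center=None):
    """Return (u, v) coordinate grids for an orientation.

    ``u`` is the wave axis (perpendicular to the bars of a grating at the
    given orientation), ``v`` the bar axis.  A grating of orientation theta is
    ``cos(2*pi*sf*u + phase)``.
    """
    h, w = shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    th = np.deg2rad(orientation_deg)
    rr, cc = np.mgrid[:h, :w].astype(float)
    rr -= center[0]
    cc -= center[1]
    u = cc * np.cos(th) + rr * np.sin(th)
    v = -cc * np.sin(th) + rr * np.cos(th)
    return u, v


def radial_distance(shape, center=None):
    h, w = shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    rr, cc = np.mgrid[:h, :w].astype(float)
    return np.hypot(rr - center[0], cc - center[1])


def position_angle(shape, center=None):
    """Angular position of every pixel, degrees CCW-from-vertical in [0, 360)."""
    h, w = shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    rr, cc = np.mgrid[:h, :w].astype(float)
    x = cc - center[1]          # right
    y = -(rr - center[0])       # up
    return np.degrees(np.arctan2(-x, y)) % 360.0


def direction_offset(angle_deg, radius):
    """Integer (drow, dcol) offset at ``radius`` pixels in direction ``angle_deg``."""
    a = np.deg2rad(angle_deg)
    dr = -radius * np.cos(a)
    dc = -radius * np.sin(a)
    return int(np.rint(dr)), int(np.rint(dc))


def angular_distance(a, b):
    """Smallest absolute angular difference in degrees (mod 360)."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % 360.0
    return np.minimum(d, 360.0 - d)


def disc_mask(shape, diameter, center=None):
    return radial_distance(shape, center) <= diameter / 2.0
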