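"""Circular (angular) helpers.

All angles are in degrees. Directions of motion live on [0, 360) with
0 deg = rightward and counter-clockwise positive; signed angular
differences are wrapped to (-180, 180].
"""

from __future__ import annotations

import numpy as np


def wrap_deg(angle):
    """Wrap an angle (or array of angles) to the interval (-180, 180].

    The boundary case maps to +180 so that the absolute wrapped
    difference is always in [0, 180].
    """
    a = np.mod(angle, 360.0)
    a = np.where(a > 180.0, a - 360.0, a)
    if np.ndim(angle) == 0:
        return float(a)
    return a


def circular_separation(a, b):
    """Unsigned circular separation between two directions, in [0, 180]."""
    return np.abs(wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))


def unit_vector(direction_deg):
    """Unit (x, y) vector(s) for direction(s) in degrees."""
    rad = np.deg2rad(direction_deg)
    return np.stack([np.cos(rad), np.sin(rad)], axis=-1)


def pairwise_min_separation(directions):
    """Minimum pairwise circular separation within each row of directions.

    Parameters
    ----------
    directions : array of shape (..., k)

    Returns
    -------
    array of shape (...,) with the smallest pairwise separation.
    """
    d = np.asarray(directions, dtype=float)
    diff = d[..., :, None] - d[..., None, :]
    sep = np.abs(wrap_deg(diff))
    k = d.shape[-1]
    iu = np.triu_indices(k, 1)
    return sep[..., iu[0], iu[1]].min(axis=-1)
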