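"""Circular arithmetic on angles in degrees.

All angles in this package are counter-clockwise from the +x axis and are
reduced to [0, 360). Differences are taken along the shorter arc, so they
live in [0, 180].
"""

from __future__ import annotations

import numpy as np


def wrap_deg(angle):
    """Reduce an angle (scalar or array) to [0, 360)."""
    return np.mod(angle, 360.0)


def circular_abs_diff_deg(a, b):
    """Absolute angular separation along the shorter arc, in [0, 180]."""
    d = np.abs(np.mod(np.asarray(a, dtype=float) - b, 360.0))
    return np.minimum(d, 360.0 - d)


def signed_circular_diff_deg(a, b):
    """Signed difference a - b mapped to (-180, 180]."""
    d = np.mod(np.asarray(a, dtype=float) - b, 360.0)
    return np.where(d > 180.0, d - 360.0, d)


def circular_interp_deg(t: np.ndarray, t0: float, a0: float, t1: float, a1: float):
    """Linear interpolation from angle ``a0`` at ``t0`` to ``a1`` at ``t1``.

    Interpolates along the shorter arc between the two angles; ``t`` may be a
    scalar or array within [t0, t1]. Returns angles in [0, 360).
    """
    if t1 == t0:
        return wrap_deg(np.full_like(np.asarray(t, dtype=float), a0))
    frac = (np.asarray(t, dtype=float) - t0) / (t1 - t0)
    delta = signed_circular_diff_deg(a1, a0)
    return wrap_deg(a0 + frac * delta)
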