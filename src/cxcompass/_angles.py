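"""Angle conventions and wrapping helpers.

Global convention: headings are in radians, counter-clockwise positive,
0 along the +x world axis, wrapped to (-pi, pi].  Egocentric bearings are
in degrees, wrapped to (-180, 180], counter-clockwise positive, 0 dead
ahead.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_rad", "wrap_deg", "circ_dist_rad"]


def wrap_rad(theta):
    """Wrap angle(s) in radians to the interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = -(-(theta + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped if wrapped.ndim else float(wrapped)


def wrap_deg(theta):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = -(-(theta + 180.0) % 360.0 - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def circ_dist_rad(a, b):
    """Signed circular difference a - b, wrapped to (-pi, pi]."""
    return wrap_rad(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
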