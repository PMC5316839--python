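"""Angle conventions shared across modules.

Orientations are axial quantities: a fibre pointing "up" and one pointing
"down" are the same fibre.  Throughout the package orientations live in
degrees in the half-open interval [-90, 90), measured counterclockwise from
the image x-axis (columns), with y pointing up.  Because arrays are stored
row-major with the row index increasing downwards, a displacement
(drow, dcol) has direction atan2(-drow, dcol).
"""

from __future__ import annotations

import numpy as np


def wrap_orientation(angle_deg):
    """Fold angles (degrees) into the axial range [-90, 90)."""
    return (np.asarray(angle_deg, dtype=float) + 90.0) % 180.0 - 90.0


def segment_orientation_deg(r0, c0, r1, c1):
    """Orientation of the segment (r0, c0) -> (r1, c1) in [-90, 90) degrees."""
    return wrap_orientation(np.degrees(np.arctan2(-(np.asarray(r1) - r0), np.asarray(c1) - c0)))


def radial_bearing_deg(rows, cols, centre_rc):
    """Axial bearing of each pixel as seen from ``centre_rc`` in [-90, 90)."""
    drow = np.asarray(rows, dtype=float) - centre_rc[0]
    dcol = np.asarray(cols, dtype=float) - centre_rc[1]
    return wrap_orientation(np.degrees(np.arctan2(-drow, dcol)))


def angular_difference_deg(a, b):
    """Smallest axial difference |a - b| on the 180-degree circle."""
    d = np.abs(wrap_orientation(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))
    return np.minimum(d, 180.0 - d)
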