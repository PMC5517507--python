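"""Canonical fundus frame and signed-angle conventions.

All lateral geometry lives in a right-eye-format fundus frame:

* origin at the fovea, coordinates in millimetres;
* ``+x`` temporal, ``+y`` superior;
* left eyes are mirrored about the vertical axis (``x -> -x``) on ingestion so
  that temporal/nasal and all signed angles are comparable across eyes.

Depth is positive-posterior, in micrometres, measured from the most anterior
rendered coronal section (section index 0 is most anterior).

Signed angles follow the clinical caliper convention: measured from the
temporal horizontal meridian, *inferior positive*.  With ``+y`` superior this
is ``atan2(-dy, dx)``.  Under this convention the fovea sits at a small
positive disc-fovea angle (it lies 2-6 deg inferior to the disc), a deepest
point in the inferior hemisphere has a positive disc-DPE angle, and
inferotemporal disc torsion is positive.

Line orientations (for the disc long axis and meridians, which have no
preferred pole) are reduced to ``(-90, 90]`` degrees.
"""

from __future__ import annotations

import math

import numpy as np

#: Lateral scan field, mm (12 x 9 raster centred on the fovea).
FIELD_WIDTH_MM = 12.0
FIELD_HEIGHT_MM = 9.0
FIELD_X_MM = (-6.0, 6.0)
FIELD_Y_MM = (-4.5, 4.5)

#: Default lateral raster and pitch (square pixels, 12/512 = 0.0234375 mm).
DEFAULT_NX = 512
DEFAULT_NY = 384
DEFAULT_LATERAL_PITCH_MM = FIELD_WIDTH_MM / DEFAULT_NX

#: Scanner axial geometry: 1,000 coronal sections spanning 2.6 mm of tissue,
#: i.e. 2.6 um per section.
DEFAULT_N_SECTIONS = 1000
DEFAULT_SECTION_PITCH_UM = 2.6


def wrap_angle_deg(angle: float) -> float:
    """Wrap an angle to ``(-180, 180]`` degrees."""
    wrapped = math.fmod(float(angle) + 180.0, 360.0)
    if wrapped <= 0.0:
        wrapped += 360.0
    return wrapped - 180.0


def wrap_line_deg(angle: float) -> float:
    """Wrap an (unoriented) line angle to ``(-90, 90]`` degrees."""
    wrapped = math.fmod(float(angle) + 90.0, 180.0)
    if wrapped <= 0.0:
        wrapped += 180.0
    return wrapped - 90.0


def signed_angle_deg(origin, target) -> float:
    """Inferior-positive angle of the ray ``origin -> target``.

    Measured from the temporal (+x) horizontal meridian through ``origin``.
    """
    dx = float(target[0]) - float(origin[0])
    dy = float(target[1]) - float(origin[1])
    return math.degrees(math.atan2(-dy, dx))


def line_orientation_deg(direction) -> float:
    """Inferior-positive orientation of a line with canonical-frame direction.

    Returns the line angle from the horizontal in ``(-90, 90]``.
    """
    dx, dy = float(direction[0]), float(direction[1])
    return wrap_line_deg(math.degrees(math.atan2(-dy, dx)))


def deviation_from_vertical_deg(direction) -> float:
    """Signed deviation of a line from the image vertical, in ``(-90, 90]``.

    Positive in the inferior-positive rotational sense (for the disc long
    axis this makes inferotemporal torsion positive).
    """
    return wrap_line_deg(line_orientation_deg(direction) - 90.0)


def unit(v) -> np.ndarray:
    """Return ``v`` normalised to unit length."""
    v = np.asarray(v, dtype=float)
    n = float(np.hypot(v[0], v[1]))
    if n == 0.0:
        raise ValueError("cannot normalise a zero vector")
    return v / n


def inferior_normal(direction) -> np.ndarray:
    """Unit normal of ``direction`` pointing toward the inferior side.

    For the disc-fovea axis this is the normal used to split the fundus into
    superior/inferior hemispheres: with ``+y`` superior the inferior-pointing
    perpendicular of ``(tx, ty)`` is ``(ty, -tx)``.
    """
    t = unit(direction)
    return np.array([t[1], -t[0]])
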