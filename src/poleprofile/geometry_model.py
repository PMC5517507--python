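"""DPE location classification and the geometric disc-configuration model.

The four-region classification assigns each eye's DPE to ``near_fovea``
(within 3000 um of the fovea), ``near_disc`` (within 3000 um of the disc
center), or the ``superior``/``inferior`` hemisphere split by the extended
fovea-disc line.  The geometric model treats the tilted disc as a circle
imaged on an oblique plane: its projection foreshortens by ``cos(tilt)``
along the tilt direction (ovality ``1/cos``), the long axis lies
perpendicular to the disc-to-DPE direction, and therefore the disc-DPE angle
decomposes as disc torsion plus the disc-fovea angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .conventions import (
    deviation_from_vertical_deg,
    inferior_normal,
    unit,
    wrap_line_deg,
)
from .synthetic_eye import Landmarks

__all__ = [
    "DPECategory",
    "CLASSIFICATION_RADIUS_UM",
    "classify_dpe",
    "project_disc",
    "predict_torsion",
    "predict_ovality",
]

CLASSIFICATION_RADIUS_UM = 3000.0
CATEGORY_LABELS = ("near_fovea", "superior", "inferior", "near_disc")


@dataclass(frozen=True)
class DPECategory:
    """Assigned DPE location category with the two landmark distances."""

    label: str
    distance_to_fovea_um: float
    distance_to_disc_um: float

    def __post_init__(self) -> None:
        if self.label not in CATEGORY_LABELS:
            raise ValueError(f"unknown category label {self.label!r}")


def classify_dpe(dpe_center_mm, landmarks: Landmarks) -> DPECategory:
    """Four-region DPE classification.

    Precedence: near-fovea, then near-disc (both radii inclusive at exactly
    3000 um), then the hemisphere split; a DPE exactly on the extended
    fovea-disc line beyond both radii ties to ``inferior``.
    """
    p = np.asarray(dpe_center_mm, dtype=float)
    f = np.asarray(landmarks.fovea_mm, dtype=float)
    c = np.asarray(landmarks.disc_center_mm, dtype=float)
    d_fovea = float(np.hypot(*(p - f))) * 1000.0
    d_disc = float(np.hypot(*(p - c))) * 1000.0
    if d_fovea <= CLASSIFICATION_RADIUS_UM:
        label = "near_fovea"
    elif d_disc <= CLASSIFICATION_RADIUS_UM:
        label = "near_disc"
    else:
        i_hat = inferior_normal(f - c)
        side = float(np.dot(p - f, i_hat))
        label = "inferior" if side >= 0.0 else "superior"
    return DPECategory(label=label, distance_to_fovea_um=d_fovea, distance_to_disc_um=d_disc)


def project_disc(
    disc_radius_mm: float, tilt_downhill, tilt_deg: float
) -> tuple[float, float, float]:
    """Orthographic en-face projection of a circular disc on a tilted plane.

    Returns ``(LD um, SD um, long-axis deviation from image vertical, deg)``.
    The circle keeps its diameter ``2r`` along the level axis (the long
    axis, perpendicular to the downhill/tilt direction) and foreshortens to
    ``2r cos(tilt)`` along the downhill direction.
    """
    if not (0.0 <= tilt_deg < 90.0):
        raise ValueError("tilt_deg must be in [0, 90)")
    if disc_radius_mm <= 0:
        raise ValueError("disc_radius_mm must be > 0")
    ld = 2000.0 * disc_radius_mm
    sd = ld * math.cos(math.radians(tilt_deg))
    u_hat = unit(tilt_downhill)
    long_axis = np.array([-u_hat[1], u_hat[0]])
    return ld, sd, deviation_from_vertical_deg(long_axis)


def predict_torsion(disc_dpe_angle_deg: float, disc_fovea_angle_deg: float) -> float:
    """Model-predicted torsion: disc-DPE angle minus disc-fovea angle.

    The disc-DPE angle is the sum of the torsion and the disc-fovea angle
    when the disc plane is pulled toward the DPE; wrapped to ``(-90, 90]``.
    """
    return wrap_line_deg(float(disc_dpe_angle_deg) - float(disc_fovea_angle_deg))


def predict_ovality(tilt_deg: float) -> float:
    """Model-predicted ovality of an obliquely imaged circular disc."""
    if not (0.0 <= tilt_deg < 90.0):
        raise ValueError("tilt_deg must be in [0, 90)")
    return 1.0 / math.cos(math.radians(tilt_deg))
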