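"""The six DPE-relative posterior-pole metrics.

Distances are straight-line in-plane distances (um) measured at the coronal
plane of the DPE; depths are signed section-count differences converted at
the per-section pitch (2.6 um by default), positive when the DPE lies
posterior to the reference interface; angles are inferior-positive and
measured from the horizontal meridian through the disc center (see
:mod:`poleprofile.conventions`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .conventions import signed_angle_deg
from .dpe_detection import DepthMapResult, DPEResult
from .synthetic_eye import Landmarks

__all__ = [
    "PosteriorPoleMetrics",
    "planar_metrics",
    "depth_between",
    "temporal_border_section",
    "fovea_section",
    "posterior_pole_metrics",
]

_COINCIDENT_UM = 1e-6


@dataclass(frozen=True)
class PosteriorPoleMetrics:
    """Disc/fovea-referenced DPE position metrics.

    ``disc_dpe_depth_um``: positive = DPE posterior to the temporal disc
    border interface.  ``fovea_dpe_depth_um``: positive = DPE posterior to
    the foveal interface.  ``disc_dpe_angle_deg``/``disc_fovea_angle_deg``:
    inferior-positive angles at the disc center.
    """

    disc_dpe_distance_um: float
    fovea_dpe_distance_um: float
    disc_dpe_depth_um: float
    fovea_dpe_depth_um: float
    disc_dpe_angle_deg: float
    disc_fovea_angle_deg: float
    flags: frozenset = field(default_factory=frozenset)


def depth_between(section_a: int, section_b: int, section_pitch_um: float) -> float:
    """Signed depth (um) between two coronal sections.

    Exactly ``(section_a - section_b) * pitch``: one section of separation is
    2.6 um at the default pitch, and the full 1,000-section stack spans
    2.6 mm.
    """
    return (int(section_a) - int(section_b)) * section_pitch_um


def temporal_border_section(landmarks: Landmarks, depth: DepthMapResult) -> int:
    """Interface section at the temporal border of the optic disc.

    The border is the most-temporal (max +x) clinical margin point; the
    depth map is sampled half a pixel inside the margin so the reading lands
    on the disc-plane side of the boundary, falling back to the nearest
    valid pixel within 100 um.
    """
    return _border_section(landmarks, depth, temporal=True)


def _border_section(landmarks: Landmarks, depth: DepthMapResult, temporal: bool) -> int:
    margin = landmarks.disc_margin
    k = int(np.argmax(margin[:, 0]) if temporal else np.argmin(margin[:, 0]))
    p = margin[k, :2]
    c = np.asarray(landmarks.disc_center_mm, dtype=float)
    inward = c - p
    norm = float(np.hypot(*inward))
    if norm > 0:
        # sample just inside the margin so the nearest pixel center cannot
        # snap to the far side of the disc boundary (0.75 px inset leaves the
        # snapped center >= 0.25 px inside)
        p = p + inward / norm * (0.75 * depth.lateral_pitch_mm)
    side = "temporal" if temporal else "nasal"
    try:
        return depth.value_at(float(p[0]), float(p[1]), max_dist_um=100.0)
    except LookupError as exc:
        raise LookupError(f"{side} disc border not resolvable: {exc}") from exc


def fovea_section(landmarks: Landmarks, depth: DepthMapResult) -> int:
    """Interface section at the fovea landmark."""
    fx, fy = landmarks.fovea_mm
    try:
        return depth.value_at(float(fx), float(fy), max_dist_um=100.0)
    except LookupError as exc:
        raise LookupError(f"foveal interface not resolvable: {exc}") from exc


def planar_metrics(dpe: DPEResult, landmarks: Landmarks) -> PosteriorPoleMetrics:
    """In-plane distances and angles (depths left as NaN).

    A DPE coincident with the disc center leaves the disc-DPE angle
    undefined (NaN) and sets the ``angle_undefined`` flag.
    """
    dx = (dpe.center_mm[0] - landmarks.disc_center_mm[0]) * 1000.0
    dy = (dpe.center_mm[1] - landmarks.disc_center_mm[1]) * 1000.0
    fx = (dpe.center_mm[0] - landmarks.fovea_mm[0]) * 1000.0
    fy = (dpe.center_mm[1] - landmarks.fovea_mm[1]) * 1000.0
    disc_dist = math.hypot(dx, dy)
    flags = set()
    if disc_dist < _COINCIDENT_UM:
        disc_angle = math.nan
        flags.add("angle_undefined")
    else:
        disc_angle = signed_angle_deg(landmarks.disc_center_mm, dpe.center_mm)
    return PosteriorPoleMetrics(
        disc_dpe_distance_um=disc_dist,
        fovea_dpe_distance_um=math.hypot(fx, fy),
        disc_dpe_depth_um=math.nan,
        fovea_dpe_depth_um=math.nan,
        disc_dpe_angle_deg=disc_angle,
        disc_fovea_angle_deg=landmarks.disc_fovea_angle_deg,
        flags=frozenset(flags),
    )


def posterior_pole_metrics(
    dpe: DPEResult, landmarks: Landmarks, depth: DepthMapResult
) -> PosteriorPoleMetrics:
    """All six DPE metrics, combining in-plane geometry with the depth map."""
    planar = planar_metrics(dpe, landmarks)
    pitch = depth.section_pitch_um
    disc_depth = depth_between(
        dpe.section_index, temporal_border_section(landmarks, depth), pitch
    )
    fovea_depth = depth_between(dpe.section_index, fovea_section(landmarks, depth), pitch)
    return PosteriorPoleMetrics(
        disc_dpe_distance_um=planar.disc_dpe_distance_um,
        fovea_dpe_distance_um=planar.fovea_dpe_distance_um,
        disc_dpe_depth_um=disc_depth,
        fovea_dpe_depth_um=fovea_depth,
        disc_dpe_angle_deg=planar.disc_dpe_angle_deg,
        disc_fovea_angle_deg=planar.disc_fovea_angle_deg,
        flags=planar.flags,
    )
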