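"""Optic-disc configuration: ovality, torsion, horizontal/vertical tilt.

Ovality (tilt ratio) is LD/SD, the ratio of the longest to shortest disc
diameter from a least-squares ellipse fit of the clinical margin points.
Torsion is the signed deviation of the disc long axis from the
fovea-referenced vertical meridian (perpendicular to the disc-fovea line),
positive for inferotemporal torsion.  Tilt angles come from cross-sections:
the angle between the chord joining the two clinical margin interface points
(the ONH plane) and the chord joining the Bruch's-membrane inner tips just
outside the disc (the reference plane), measured along the disc-fovea axis
(horizontal tilt; temporal-down positive) and its perpendicular through the
disc center (vertical tilt; inferior-down positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .conventions import inferior_normal, wrap_line_deg
from .dpe_detection import DepthMapResult
from .synthetic_eye import Landmarks

__all__ = [
    "EllipseFit",
    "DiscConfig",
    "OVALITY_TORSION_MIN",
    "fit_disc_ellipse",
    "torsion",
    "tilt_from_cross_section",
    "measure_disc",
]

#: Below this ovality the long-axis orientation is numerically unstable and
#: torsion is reported as 0 with ``torsion_defined = False``.
OVALITY_TORSION_MIN = 1.02


class EllipseFitError(ValueError):
    """Degenerate margin (too few or collinear points)."""


@dataclass(frozen=True)
class EllipseFit:
    """Least-squares ellipse through disc-margin points.

    ``long_axis_deviation_deg`` is the line angle of the long axis from the
    image vertical in ``(-90, 90]``, inferior-positive rotational sense;
    meaningless when ``orientation_defined`` is False (near-circular disc).
    """

    center_mm: tuple[float, float]
    long_axis_um: float
    short_axis_um: float
    long_axis_deviation_deg: float
    orientation_defined: bool

    @property
    def ovality(self) -> float:
        return self.long_axis_um / self.short_axis_um


@dataclass(frozen=True)
class DiscConfig:
    """Measured disc configuration (all signed per the fundus conventions)."""

    long_axis_um: float
    short_axis_um: float
    ovality: float
    torsion_deg: float
    torsion_defined: bool
    h_tilt_deg: float
    v_tilt_deg: float

    def __post_init__(self) -> None:
        if not (self.short_axis_um > 0 and self.long_axis_um >= self.short_axis_um):
            raise ValueError("ellipse axes must satisfy LD >= SD > 0")


def _conic_lstsq(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Direct least-squares ellipse-specific conic fit (Halir-Flusser).

    Returns the conic coefficients ``(A, B, C, D, E, F)`` of
    ``A x^2 + B xy + C y^2 + D x + E y + F = 0`` with the ellipse constraint
    ``4AC - B^2 = 1`` built into the eigenproblem, which makes the fit
    stable on exact and near-degenerate data.
    """
    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise EllipseFitError("degenerate margin configuration") from exc
    m = s1 + s2 @ t
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    eigval, eigvec = np.linalg.eig(m)
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    good = np.nonzero((cond > 0) & np.isreal(eigval))[0]
    if good.size == 0:
        raise EllipseFitError("no ellipse solution for the margin points")
    a1 = np.real(eigvec[:, good[0]])
    return np.concatenate([a1, t @ a1])


def fit_disc_ellipse(points_mm: np.ndarray) -> EllipseFit:
    """Fit an ellipse to 2D margin points (mm) and extract LD/SD/orientation.

    Least-squares conic fit (points are centered and scaled first for
    conditioning), then geometric parameters from the eigen-decomposition of
    the quadratic part.  Requires >= 5 non-collinear points; collinear
    margins raise :class:`EllipseFitError`.
    """
    pts = np.asarray(points_mm, dtype=float)
    if pts.ndim != 2 or pts.shape[1] < 2 or pts.shape[0] < 5:
        raise EllipseFitError("need at least 5 margin points with (x, y)")
    xy = pts[:, :2]
    spread = np.linalg.svd(xy - xy.mean(axis=0), compute_uv=False)
    if spread[-1] < 1e-9 * max(spread[0], 1e-12):
        raise EllipseFitError("margin points are collinear")

    # fit in image coordinates (x temporal, y inferior-positive) so the
    # rotation comes out directly in the clinical sign convention
    u = xy[:, 0]
    v = -xy[:, 1]
    mu, mv = u.mean(), v.mean()
    scale = float(np.hypot(u - mu, v - mv).mean()) or 1.0
    A, B, C, D, E, F = _conic_lstsq((u - mu) / scale, (v - mv) / scale)

    quad = np.array([[A, B / 2.0], [B / 2.0, C]])
    lam, vec = np.linalg.eigh(quad)
    if lam[0] * lam[1] <= 0:
        raise EllipseFitError("margin points do not describe an ellipse")
    try:
        center_n = np.linalg.solve(2.0 * quad, [-D, -E])
    except np.linalg.LinAlgError as exc:
        raise EllipseFitError("degenerate conic") from exc
    f_centered = (
        A * center_n[0] ** 2
        + B * center_n[0] * center_n[1]
        + C * center_n[1] ** 2
        + D * center_n[0]
        + E * center_n[1]
        + F
    )
    with np.errstate(invalid="raise"):
        try:
            semis = np.sqrt(-f_centered / lam) * scale
        except FloatingPointError as exc:
            raise EllipseFitError("margin points do not describe an ellipse") from exc
    k_long = int(np.argmax(semis))
    semi_long, semi_short = float(semis[k_long]), float(semis[1 - k_long])
    phi = math.atan2(vec[1, k_long], vec[0, k_long])
    xc = float(center_n[0] * scale + mu)
    yc = float(center_n[1] * scale + mv)
    ovality = semi_long / semi_short
    deviation = wrap_line_deg(math.degrees(phi) - 90.0)
    return EllipseFit(
        center_mm=(xc, -yc),
        long_axis_um=2000.0 * semi_long,
        short_axis_um=2000.0 * semi_short,
        long_axis_deviation_deg=deviation,
        orientation_defined=ovality >= OVALITY_TORSION_MIN,
    )


def torsion(fit: EllipseFit | float, landmarks: Landmarks) -> tuple[float, bool]:
    """Disc torsion: long-axis deviation from the fovea-referenced meridian.

    The vertical meridian is perpendicular to the disc-fovea line, so the
    torsion equals the long axis' deviation from the image vertical minus
    the disc-fovea angle, wrapped to ``(-90, 90]``; positive values are
    inferotemporal.  Near-circular discs return ``(0.0, False)``.

    ``fit`` may be an :class:`EllipseFit` or a bare long-axis deviation in
    degrees (then assumed defined).
    """
    if isinstance(fit, EllipseFit):
        if not fit.orientation_defined:
            return 0.0, False
        deviation = fit.long_axis_deviation_deg
    else:
        deviation = float(fit)
    return wrap_line_deg(deviation - landmarks.disc_fovea_angle_deg), True


def _margin_crossings(
    landmarks: Landmarks, d_hat: np.ndarray
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Intersect the margin polygon with the line through the disc center.

    Returns ``((u+, z+), (u-, z-))``: signed along-line coordinate (mm from
    the disc center, positive toward ``d_hat``) and interface depth (um) of
    the margin crossing on each side, linearly interpolated between the
    bracketing margin points.
    """
    c = np.asarray(landmarks.disc_center_mm, dtype=float)
    n_hat = np.array([-d_hat[1], d_hat[0]])
    rel = landmarks.disc_margin[:, :2] - c
    u = rel @ d_hat
    v = rel @ n_hat
    z = landmarks.disc_margin[:, 2]
    pos = neg = None
    n = len(u)
    for i in range(n):
        j = (i + 1) % n
        vi, vj = v[i], v[j]
        if vi == 0.0:
            cross_u, cross_z = u[i], z[i]
        elif (vi > 0) != (vj > 0):
            t = vi / (vi - vj)
            cross_u = u[i] + t * (u[j] - u[i])
            cross_z = z[i] + t * (z[j] - z[i])
        else:
            continue
        if cross_u >= 0 and (pos is None or cross_u > pos[0]):
            pos = (float(cross_u), float(cross_z))
        if cross_u < 0 and (neg is None or cross_u < neg[0]):
            neg = (float(cross_u), float(cross_z))
    if pos is None or neg is None:
        side = "positive" if pos is None else "negative"
        raise LookupError(f"margin crossing missing on the {side} side of the scan line")
    return pos, neg


_BM_TIP_OFFSET_MM = 0.3


def tilt_from_cross_section(
    axis: str, landmarks: Landmarks, depth: DepthMapResult
) -> float:
    """Tilt angle (degrees) along one cross-sectional scan line.

    ``axis``: ``"horizontal"`` scans along the disc-fovea axis (positive =
    temporal border deeper), ``"vertical"`` perpendicular to it through the
    disc center (positive = inferior border deeper).  The ONH plane chord
    uses the margin-point interface depths; the reference plane chord uses
    the depth map sampled just outside the disc margin on each side (the
    Bruch's-membrane inner tips).
    """
    if axis == "horizontal":
        d_hat = landmarks.temporal_axis()
    elif axis == "vertical":
        d_hat = inferior_normal(landmarks.temporal_axis())
    else:
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    (u_p, z_p), (u_n, z_n) = _margin_crossings(landmarks, d_hat)
    onh_angle = math.atan2((z_p - z_n) / 1000.0, u_p - u_n)

    c = np.asarray(landmarks.disc_center_mm, dtype=float)
    pitch = depth.section_pitch_um
    ny, nx = depth.sections.shape
    x_lo = depth.origin_mm[0]
    x_hi = depth.origin_mm[0] + (nx - 1) * depth.lateral_pitch_mm
    y_hi = depth.origin_mm[1]
    y_lo = depth.origin_mm[1] - (ny - 1) * depth.lateral_pitch_mm
    ref = []
    for u_edge, sign, side in ((u_p, 1.0, "temporal/inferior"), (u_n, -1.0, "nasal/superior")):
        p = c + d_hat * (u_edge + sign * _BM_TIP_OFFSET_MM)
        # a far-nasal disc can push the tip sample off the raster; clamp onto
        # the field edge, where the peripapillary wall is still smooth
        p = np.array([min(max(p[0], x_lo), x_hi), min(max(p[1], y_lo), y_hi)])
        try:
            ref.append((u_edge + sign * _BM_TIP_OFFSET_MM, depth.value_at(p[0], p[1]) * pitch))
        except (LookupError, ValueError) as exc:
            raise LookupError(f"Bruch's membrane tip missing on the {side} side: {exc}") from exc
    (ur_p, zr_p), (ur_n, zr_n) = ref
    ref_angle = math.atan2((zr_p - zr_n) / 1000.0, ur_p - ur_n)
    return math.degrees(onh_angle - ref_angle)


def measure_disc(landmarks: Landmarks, depth: DepthMapResult) -> DiscConfig:
    """Full disc configuration from margin landmarks and the depth map."""
    fit = fit_disc_ellipse(landmarks.disc_margin[:, :2])
    tors, defined = torsion(fit, landmarks)
    return DiscConfig(
        long_axis_um=fit.long_axis_um,
        short_axis_um=fit.short_axis_um,
        ovality=fit.ovality,
        torsion_deg=tors,
        torsion_defined=defined,
        h_tilt_deg=tilt_from_cross_section("horizontal", landmarks, depth),
        v_tilt_deg=tilt_from_cross_section("vertical", landmarks, depth),
    )
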