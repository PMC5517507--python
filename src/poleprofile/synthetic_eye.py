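"""Ground-truthed posterior-pole eye phantoms and en-face volume rendering.

The phantom models the posterior globe wall as a smooth depth surface
``z(x, y)`` (micrometres, positive-posterior) composed of

* a spherical base cap of configurable radius, tangent to the coronal plane
  at the fovea (the scan field is centred on fixation), and
* a single localized Gaussian outpouching ("staphyloma-like bump") that
  places the deepest point of the eyeball (DPE) away from the tangency point.

The renderer slices the surface into coronal en-face sections the way a
swept-source OCT C-scan stack does: a hyper-reflective Bruch's-membrane band
over darker choroid, dim retina anterior of the band, multiplicative speckle,
1,000 sections of 2.6 um by default over a 12 x 9 mm raster.  The posterior
edge of the bright band is the Bruch's-membrane/choroid interface, i.e. the
depth surface the detector is asked to recover.

Cohort simulation draws per-eye anatomy and covariates from per-group
distributions shaped like a myopic vs emmetropic clinical series and yields
(truth manifest, volume, as-scanned landmarks) triples; left eyes are
generated mirrored.  Re-scans replay the same anatomy with fresh speckle and
a small fixation offset for reproducibility (ICC) studies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Sequence

import numpy as np

from .conventions import (
    DEFAULT_N_SECTIONS,
    DEFAULT_NX,
    DEFAULT_NY,
    DEFAULT_SECTION_PITCH_UM,
    FIELD_HEIGHT_MM,
    FIELD_WIDTH_MM,
    FIELD_X_MM,
    FIELD_Y_MM,
    deviation_from_vertical_deg,
    inferior_normal,
    signed_angle_deg,
    unit,
    wrap_line_deg,
)

log = logging.getLogger(__name__)

__all__ = [
    "SurfaceModel",
    "Landmarks",
    "DiscTilt",
    "EnFaceVolume",
    "RenderParams",
    "EyeTruth",
    "SimulatedEye",
    "RescanResult",
    "RescanSpec",
    "GroupSpec",
    "CohortSpec",
    "build_surface",
    "place_landmarks",
    "disc_plane_offset_um",
    "render_enface",
    "rendered_depth_um",
    "simulate_truths",
    "simulate_cohort",
    "rescan",
    "default_cohort_spec",
    "mirror_surface",
    "mirror_landmarks",
    "mirror_volume",
]


class PhantomParameterError(ValueError):
    """Invalid phantom/render parameter."""


class RenderRangeError(ValueError):
    """Surface depth does not fit into the configured axial span."""


# --------------------------------------------------------------------------
# Surface
# --------------------------------------------------------------------------

_MIN_BASE_RADIUS_MM = 10.0  # keeps the spherical cap single-valued over the field


@dataclass(frozen=True)
class SurfaceModel:
    """Continuous posterior-pole depth surface with one dominant bump.

    ``depth_um`` is positive-posterior relative to the tangency point of the
    base sphere; the renderer re-references it to the anterior edge of the
    scanned slab.  ``base_radius_mm`` may be ``inf`` for a flat base.
    ``base_center_mm`` is the tangency point (the fovea for a fixating eye);
    re-scans with a fixation offset translate it together with the bump.
    """

    base_radius_mm: float
    bump_center_mm: tuple[float, float]
    bump_amplitude_um: float
    bump_sigma_mm: float
    axial_length_mm: float = 24.0
    base_center_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.base_radius_mm >= _MIN_BASE_RADIUS_MM):
            raise PhantomParameterError(
                f"base_radius_mm must be >= {_MIN_BASE_RADIUS_MM} mm (or inf), "
                f"got {self.base_radius_mm}"
            )
        if not (self.bump_sigma_mm > 0):
            raise PhantomParameterError(f"bump_sigma_mm must be > 0, got {self.bump_sigma_mm}")
        if not (self.bump_amplitude_um >= 0):
            raise PhantomParameterError(
                f"bump_amplitude_um must be >= 0, got {self.bump_amplitude_um}"
            )
        if not all(math.isfinite(c) for c in self.bump_center_mm):
            raise PhantomParameterError("bump_center_mm must be finite")

    def depth_um(self, x, y) -> np.ndarray:
        """Evaluate the depth surface (um, positive-posterior) at (x, y) mm."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        bx, by = self.bump_center_mm
        bump = self.bump_amplitude_um * np.exp(
            -((x - bx) ** 2 + (y - by) ** 2) / (2.0 * self.bump_sigma_mm**2)
        )
        if math.isfinite(self.base_radius_mm):
            cx, cy = self.base_center_mm
            r2 = (x - cx) ** 2 + (y - cy) ** 2
            R = self.base_radius_mm
            sag_mm = R - np.sqrt(np.maximum(R * R - r2, 0.0))
            base = -1000.0 * sag_mm
        else:
            base = np.zeros_like(bump)
        return base + bump

    def argmax_depth(
        self,
        extra_depth: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
        step_mm: float = 0.01,
    ) -> tuple[float, float, float]:
        """Dense-grid argmax of the surface over the scan field.

        Evaluates on a ``step_mm`` grid (10 um by default) and returns
        ``(x, y, depth_um)``.  ``extra_depth`` adds a further depth term
        (e.g. the optic-disc plane imprint) before taking the maximum.
        """
        xs = np.arange(FIELD_X_MM[0], FIELD_X_MM[1] + step_mm / 2, step_mm)
        ys = np.arange(FIELD_Y_MM[0], FIELD_Y_MM[1] + step_mm / 2, step_mm)
        best = (-np.inf, 0.0, 0.0)
        # chunk rows to bound memory on the 1201 x 901 grid
        for lo in range(0, ys.size, 128):
            yc = ys[lo : lo + 128]
            X, Y = np.meshgrid(xs, yc)
            Z = self.depth_um(X, Y)
            if extra_depth is not None:
                Z = Z + extra_depth(X, Y)
            k = int(np.argmax(Z))
            zmax = float(Z.flat[k])
            if zmax > best[0]:
                best = (zmax, float(X.flat[k]), float(Y.flat[k]))
        return best[1], best[2], best[0]


def build_surface(
    base_radius_mm: float,
    bump_center_mm: tuple[float, float],
    bump_amplitude_um: float,
    bump_sigma_mm: float,
    axial_length_mm: float = 24.0,
) -> SurfaceModel:
    """Construct a validated :class:`SurfaceModel` (see class docs)."""
    return SurfaceModel(
        base_radius_mm=base_radius_mm,
        bump_center_mm=tuple(map(float, bump_center_mm)),
        bump_amplitude_um=float(bump_amplitude_um),
        bump_sigma_mm=float(bump_sigma_mm),
        axial_length_mm=float(axial_length_mm),
    )


# --------------------------------------------------------------------------
# Landmarks / disc plane
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DiscTilt:
    """Local tilt of the optic-nerve-head plane.

    ``downhill_azimuth_deg`` is the inferior-positive fundus angle of the
    direction in which the disc plane dips posteriorly (for a disc pulled
    toward the DPE this points at the DPE); ``tilt_deg`` is the dihedral
    angle between the disc plane and the coronal plane.
    """

    downhill_azimuth_deg: float
    tilt_deg: float

    def downhill(self) -> np.ndarray:
        a = math.radians(self.downhill_azimuth_deg)
        # inferior-positive angle -> canonical (+y superior) direction
        return np.array([math.cos(a), -math.sin(a)])


@dataclass(frozen=True)
class Landmarks:
    """Disc and fovea landmarks in the canonical fundus frame.

    ``disc_margin`` is an (N, 3) array of clinical Bruch's-membrane-opening
    margin points, ``(x mm, y mm, z um)``; z is absolute surface depth (same
    reference as :meth:`SurfaceModel.depth_um`).  ``tilt_downhill`` is the
    unit direction along which the disc plane dips posteriorly (undefined
    content when ``tilt_deg`` is 0).
    """

    fovea_mm: tuple[float, float]
    disc_center_mm: tuple[float, float]
    disc_radius_mm: float
    disc_margin: np.ndarray
    tilt_downhill: tuple[float, float]
    tilt_deg: float
    laterality: str = "right"

    def __post_init__(self) -> None:
        margin = np.asarray(self.disc_margin, dtype=float)
        if margin.ndim != 2 or margin.shape[1] != 3 or margin.shape[0] < 8:
            raise PhantomParameterError("disc_margin must be an (N>=8, 3) array")
        object.__setattr__(self, "disc_margin", margin)
        if not (self.disc_radius_mm > 0):
            raise PhantomParameterError("disc_radius_mm must be > 0")
        if not (0.0 <= self.tilt_deg < 90.0):
            raise PhantomParameterError("tilt_deg must be in [0, 90)")
        if self.laterality not in ("right", "left"):
            raise PhantomParameterError("laterality must be 'right' or 'left'")

    @property
    def disc_fovea_angle_deg(self) -> float:
        """Inferior-positive angle of the disc-center -> fovea ray."""
        return signed_angle_deg(self.disc_center_mm, self.fovea_mm)

    @property
    def disc_fovea_distance_mm(self) -> float:
        return float(np.hypot(
            self.fovea_mm[0] - self.disc_center_mm[0],
            self.fovea_mm[1] - self.disc_center_mm[1],
        ))

    def temporal_axis(self) -> np.ndarray:
        """Unit vector along the disc->fovea axis (points temporal)."""
        return unit(np.subtract(self.fovea_mm, self.disc_center_mm))


def disc_plane_offset_um(x, y, landmarks: Landmarks) -> np.ndarray:
    """Posterior depth offset imprinted by the tilted disc plane.

    Inside the projected disc-margin ellipse the Bruch's-membrane surface is
    dragged onto the tilted ONH plane: offset ``1000 * tan(tilt) * s`` where
    ``s`` is the signed lateral coordinate along the downhill direction.
    Outside the margin the offset is zero (the peripapillary Bruch's membrane
    is left on the smooth globe wall).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if landmarks.tilt_deg == 0.0:
        return np.zeros(np.broadcast(x, y).shape)
    theta = math.radians(landmarks.tilt_deg)
    u_hat = unit(landmarks.tilt_downhill)
    a_hat = np.array([-u_hat[1], u_hat[0]])  # long (level) axis of the ellipse
    cx, cy = landmarks.disc_center_mm
    r = landmarks.disc_radius_mm
    du = (x - cx) * u_hat[0] + (y - cy) * u_hat[1]
    da = (x - cx) * a_hat[0] + (y - cy) * a_hat[1]
    inside = (da / r) ** 2 + (du / (r * math.cos(theta))) ** 2 <= 1.0 + 1e-9
    return np.where(inside, 1000.0 * math.tan(theta) * du, 0.0)


def place_landmarks(
    surface: SurfaceModel,
    disc_offset_mm: float = 4.6,
    disc_radius_mm: float = 0.85,
    disc_fovea_angle_deg: float = 4.0,
    tilt: DiscTilt | None = None,
    laterality: str = "right",
    n_margin: int = 72,
) -> Landmarks:
    """Place fovea, disc center and disc margin on the phantom surface.

    The fovea sits at the frame origin; the disc center is ``disc_offset_mm``
    away on the nasal side, elevated so that the disc->fovea ray makes the
    requested inferior-positive ``disc_fovea_angle_deg``.  The margin is a
    circle of ``disc_radius_mm`` drawn in the (possibly tilted) disc plane;
    its en-face projection is therefore an ellipse foreshortened by
    ``cos(tilt)`` along the downhill direction, and margin depths follow the
    tilted plane added to the local surface depth.
    """
    if disc_offset_mm <= disc_radius_mm:
        raise PhantomParameterError(
            f"disc (radius {disc_radius_mm} mm) would overlap the fovea at "
            f"offset {disc_offset_mm} mm"
        )
    if n_margin < 8:
        raise PhantomParameterError("n_margin must be >= 8")
    alpha = math.radians(disc_fovea_angle_deg)
    center = (-disc_offset_mm * math.cos(alpha), disc_offset_mm * math.sin(alpha))

    if tilt is None or tilt.tilt_deg == 0.0:
        theta = 0.0
        u_hat = np.array([1.0, 0.0])
    else:
        if not (0.0 <= tilt.tilt_deg < 90.0):
            raise PhantomParameterError("tilt_deg must be in [0, 90)")
        theta = math.radians(tilt.tilt_deg)
        u_hat = unit(tilt.downhill())
    a_hat = np.array([-u_hat[1], u_hat[0]])

    t = np.linspace(0.0, 2.0 * math.pi, n_margin, endpoint=False)
    r = disc_radius_mm
    mx = center[0] + r * np.cos(t) * a_hat[0] + r * math.cos(theta) * np.sin(t) * u_hat[0]
    my = center[1] + r * np.cos(t) * a_hat[1] + r * math.cos(theta) * np.sin(t) * u_hat[1]
    lm_flat = Landmarks(
        fovea_mm=(0.0, 0.0),
        disc_center_mm=center,
        disc_radius_mm=r,
        disc_margin=np.column_stack([mx, my, np.zeros_like(mx)]),
        tilt_downhill=(float(u_hat[0]), float(u_hat[1])),
        tilt_deg=math.degrees(theta),
        laterality=laterality,
    )
    mz = surface.depth_um(mx, my) + disc_plane_offset_um(mx, my, lm_flat)
    lm = replace(lm_flat, disc_margin=np.column_stack([mx, my, mz]))
    if laterality == "left":
        lm = mirror_landmarks(lm)
    return lm


# --------------------------------------------------------------------------
# En-face volume and rendering
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EnFaceVolume:
    """Stack of coronal en-face sections with lateral/axial pitch metadata.

    ``intensities`` has shape ``(n_sections, ny, nx)`` (section index
    increases posteriorly, 0-based).  ``origin_mm`` is the canonical-frame
    position of the *center* of pixel ``(row=0, col=0)``; columns step by
    ``+lateral_pitch_mm`` in x and rows by ``-lateral_pitch_mm`` in y.
    """

    intensities: np.ndarray
    lateral_pitch_mm: float
    section_pitch_um: float
    origin_mm: tuple[float, float]
    laterality: str = "right"

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise PhantomParameterError("intensities must be (n_sections, ny, nx)")
        object.__setattr__(self, "intensities", arr)
        if not (self.lateral_pitch_mm > 0):
            raise PhantomParameterError("lateral_pitch_mm must be > 0")
        if not (self.section_pitch_um > 0):
            raise PhantomParameterError("section_pitch_um must be > 0")
        if self.laterality not in ("right", "left"):
            raise PhantomParameterError("laterality must be 'right' or 'left'")

    @property
    def n_sections(self) -> int:
        return int(self.intensities.shape[0])

    @property
    def shape_lateral(self) -> tuple[int, int]:
        """(ny, nx)."""
        return self.intensities.shape[1], self.intensities.shape[2]

    @property
    def axial_span_um(self) -> float:
        """Total imaged tissue depth (n_sections x section pitch)."""
        return self.n_sections * self.section_pitch_um

    def x_coords(self) -> np.ndarray:
        nx = self.intensities.shape[2]
        return self.origin_mm[0] + np.arange(nx) * self.lateral_pitch_mm

    def y_coords(self) -> np.ndarray:
        ny = self.intensities.shape[1]
        return self.origin_mm[1] - np.arange(ny) * self.lateral_pitch_mm

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the pixel whose center is nearest to (x, y) mm."""
        col = int(round((x - self.origin_mm[0]) / self.lateral_pitch_mm))
        row = int(round((self.origin_mm[1] - y) / self.lateral_pitch_mm))
        ny, nx = self.shape_lateral
        if not (0 <= col < nx and 0 <= row < ny):
            raise ValueError(f"point ({x}, {y}) mm outside the scanned field")
        return row, col


@dataclass(frozen=True)
class RenderParams:
    """Rendering geometry and tissue reflectivities.

    Reflectivities are relative (retina < choroid < BM band, matching the
    hyper-reflective-band-over-darker-choroid en-face appearance); speckle is
    multiplicative Gaussian with SD ``speckle_sd``.  ``band_sections`` is the
    thickness of the bright band in sections; the band's posterior edge is
    the BM/choroid interface.  ``anterior_margin_um`` is empty retina depth
    rendered anterior of the shallowest surface point.
    """

    nx: int = DEFAULT_NX
    ny: int = DEFAULT_NY
    n_sections: int = DEFAULT_N_SECTIONS
    section_pitch_um: float = DEFAULT_SECTION_PITCH_UM
    reflect_retina: float = 0.25
    reflect_choroid: float = 0.45
    reflect_band: float = 0.90
    band_sections: int = 8  # ~21 um RPE/BM complex at the default pitch
    speckle_sd: float = 0.15
    anterior_margin_um: float = 150.0
    intensity_scale: float = 30000.0

    def __post_init__(self) -> None:
        if self.nx * FIELD_HEIGHT_MM != self.ny * FIELD_WIDTH_MM:
            raise PhantomParameterError(
                f"raster {self.nx}x{self.ny} does not give square pixels over "
                f"the {FIELD_WIDTH_MM} x {FIELD_HEIGHT_MM} mm field"
            )
        if self.band_sections < 2:
            raise PhantomParameterError("band_sections must be >= 2")
        if self.speckle_sd < 0:
            raise PhantomParameterError("speckle_sd must be >= 0")
        if not (self.reflect_retina < self.reflect_band and self.reflect_choroid < self.reflect_band):
            raise PhantomParameterError("BM band must be brighter than retina and choroid")
        if self.anterior_margin_um < self.band_sections * self.section_pitch_um:
            raise PhantomParameterError(
                "anterior_margin_um must cover at least the band thickness"
            )

    @property
    def lateral_pitch_mm(self) -> float:
        return FIELD_WIDTH_MM / self.nx

    @property
    def axial_span_um(self) -> float:
        return self.n_sections * self.section_pitch_um

    def origin_mm(self) -> tuple[float, float]:
        p = self.lateral_pitch_mm
        return (FIELD_X_MM[0] + p / 2.0, FIELD_Y_MM[1] - p / 2.0)


def _lateral_grid(params: RenderParams) -> tuple[np.ndarray, np.ndarray]:
    p = params.lateral_pitch_mm
    x0, y0 = params.origin_mm()
    xs = x0 + np.arange(params.nx) * p
    ys = y0 - np.arange(params.ny) * p
    return np.meshgrid(xs, ys)


def rendered_depth_um(
    surface: SurfaceModel,
    params: RenderParams,
    landmarks: Landmarks | None = None,
) -> tuple[np.ndarray, float]:
    """Depth of the BM/choroid interface in the rendered (slab) frame.

    Returns ``(depth map over the raster, offset)`` where
    ``rendered depth = surface depth + disc imprint + offset`` and the offset
    re-references depths to the anterior edge of the slab (shallowest raster
    point at ``anterior_margin_um``).
    """
    X, Y = _lateral_grid(params)
    z = surface.depth_um(X, Y)
    if landmarks is not None and landmarks.tilt_deg > 0.0:
        z = z + disc_plane_offset_um(X, Y, landmarks)
    offset = params.anterior_margin_um - float(z.min())
    return z + offset, offset


def render_enface(
    surface: SurfaceModel,
    params: RenderParams | None = None,
    seed: int | np.random.SeedSequence | None = None,
    landmarks: Landmarks | None = None,
) -> EnFaceVolume:
    """Render the phantom into an en-face coronal section stack.

    For each lateral pixel the hyper-reflective band occupies the
    ``band_sections`` sections ending at the rasterized interface depth;
    retina is rendered anterior and choroid posterior of it.  Deterministic
    for a fixed ``seed``.  Landmarks, when given, imprint the tilted disc
    plane into the surface before slicing.
    """
    params = params or RenderParams()
    zr, _ = rendered_depth_um(surface, params, landmarks)
    smap = np.rint(zr / params.section_pitch_um).astype(np.int32)
    if int(smap.max()) >= params.n_sections:
        row, col = np.unravel_index(int(np.argmax(smap)), smap.shape)
        X, Y = _lateral_grid(params)
        raise RenderRangeError(
            f"surface depth {zr[row, col]:.1f} um at pixel (row={row}, col={col}, "
            f"x={X[row, col]:.3f} mm, y={Y[row, col]:.3f} mm) exceeds the axial span "
            f"{params.axial_span_um:.1f} um"
        )
    band_start = smap - (params.band_sections - 1)

    rng = np.random.default_rng(seed)
    vol = np.empty((params.n_sections, params.ny, params.nx), dtype=np.uint16)
    quant = {
        name: min(max(getattr(params, f"reflect_{name}") * params.intensity_scale, 0.0), 65535.0)
        for name in ("retina", "choroid", "band")
    }
    chunk = 64
    for lo in range(0, params.n_sections, chunk):
        hi = min(lo + chunk, params.n_sections)
        s = np.arange(lo, hi, dtype=np.int32)[:, None, None]
        if params.speckle_sd == 0.0:
            vol[lo:hi] = np.where(
                s > smap[None],
                np.uint16(round(quant["choroid"])),
                np.where(
                    s >= band_start[None],
                    np.uint16(round(quant["band"])),
                    np.uint16(round(quant["retina"])),
                ),
            )
            continue
        base = np.where(
            s > smap[None],
            np.float32(quant["choroid"]),
            np.where(
                s >= band_start[None],
                np.float32(quant["band"]),
                np.float32(quant["retina"]),
            ),
        )
        noise = rng.standard_normal(base.shape, dtype=np.float32)
        base *= np.float32(1.0) + np.float32(params.speckle_sd) * noise
        np.clip(base, 0.0, 65535.0, out=base)
        vol[lo:hi] = base.astype(np.uint16)

    return EnFaceVolume(
        intensities=vol,
        lateral_pitch_mm=params.lateral_pitch_mm,
        section_pitch_um=params.section_pitch_um,
        origin_mm=params.origin_mm(),
        laterality="right",
    )


# --------------------------------------------------------------------------
# Mirroring (left <-> right eye format)
# --------------------------------------------------------------------------


def mirror_surface(surface: SurfaceModel) -> SurfaceModel:
    return replace(
        surface,
        bump_center_mm=(-surface.bump_center_mm[0], surface.bump_center_mm[1]),
        base_center_mm=(-surface.base_center_mm[0], surface.base_center_mm[1]),
    )


def mirror_landmarks(lm: Landmarks) -> Landmarks:
    margin = lm.disc_margin.copy()
    margin[:, 0] = -margin[:, 0]
    return replace(
        lm,
        fovea_mm=(-lm.fovea_mm[0], lm.fovea_mm[1]),
        disc_center_mm=(-lm.disc_center_mm[0], lm.disc_center_mm[1]),
        disc_margin=margin,
        tilt_downhill=(-lm.tilt_downhill[0], lm.tilt_downhill[1]),
        laterality="left" if lm.laterality == "right" else "right",
    )


def mirror_volume(vol: EnFaceVolume) -> EnFaceVolume:
    """Mirror a volume about the vertical field axis.

    The raster is symmetric about x = 0, so pixel-center coordinates map onto
    each other exactly and the origin is unchanged.
    """
    return replace(
        vol,
        intensities=vol.intensities[:, :, ::-1].copy(),
        laterality="left" if vol.laterality == "right" else "right",
    )


def to_right_format(
    vol: EnFaceVolume, landmarks: Landmarks | None = None
) -> tuple[EnFaceVolume, Landmarks | None]:
    """Return the right-eye-format twin of a possibly left-format scan."""
    if vol.laterality == "right":
        return vol, landmarks
    return mirror_volume(vol), (mirror_landmarks(landmarks) if landmarks else None)


# --------------------------------------------------------------------------
# Truth manifests and cohort simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EyeTruth:
    """Ground-truth manifest for one simulated eye (canonical right format)."""

    eye_id: str
    group: str
    laterality: str
    surface: SurfaceModel
    landmarks: Landmarks
    render: RenderParams
    true_dpe_mm: tuple[float, float]
    true_dpe_depth_um: float  # rendered frame (from the most anterior section)
    true_dpe_section: int
    true_torsion_deg: float
    true_ovality: float
    true_h_tilt_deg: float
    true_v_tilt_deg: float
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("emmetropic", "myopic"):
            raise PhantomParameterError("group must be 'emmetropic' or 'myopic'")
        al = self.covariates.get("axial_length_mm")
        se = self.covariates.get("se_diopter")
        if al is not None:
            if al > 30.0:
                raise PhantomParameterError("axial length over 30 mm is excluded")
            if self.group == "myopic" and not (al > 24.0 and (se is None or se < -2.0)):
                raise PhantomParameterError("myopic eye violates AL>24 mm / SE<-2 D")
            if self.group == "emmetropic" and not (al < 24.0 and (se is None or se > 0.5)):
                raise PhantomParameterError("emmetropic eye violates AL<24 mm / SE>0.5 D")


@dataclass(frozen=True)
class SimulatedEye:
    """One simulated scan: canonical truth plus the as-scanned data.

    ``volume``/``scan_landmarks`` are mirrored into left-eye format when the
    eye's laterality is left; ``truth`` always stays in canonical right
    format.
    """

    truth: EyeTruth
    volume: EnFaceVolume
    scan_landmarks: Landmarks


def _true_disc_config(lm: Landmarks) -> tuple[float, float, float, float]:
    """Closed-form (torsion, ovality, h_tilt, v_tilt) of a tilted disc plane."""
    theta = math.radians(lm.tilt_deg)
    ovality = 1.0 / math.cos(theta)
    if lm.tilt_deg == 0.0:
        return 0.0, 1.0, 0.0, 0.0
    u_hat = unit(lm.tilt_downhill)
    a_hat = np.array([-u_hat[1], u_hat[0]])  # projected long axis
    torsion = wrap_line_deg(deviation_from_vertical_deg(a_hat) - lm.disc_fovea_angle_deg)
    t_hat = lm.temporal_axis()
    i_hat = inferior_normal(t_hat)
    h_tilt = math.degrees(math.atan(math.tan(theta) * float(np.dot(u_hat, t_hat))))
    v_tilt = math.degrees(math.atan(math.tan(theta) * float(np.dot(u_hat, i_hat))))
    return torsion, ovality, h_tilt, v_tilt


def make_eye_truth(
    eye_id: str,
    group: str,
    laterality: str,
    surface: SurfaceModel,
    landmarks: Landmarks,
    render: RenderParams,
    covariates: dict | None = None,
) -> EyeTruth:
    """Assemble an :class:`EyeTruth`, deriving the DPE and disc truths.

    The true DPE is the dense-grid argmax (10 um lateral step) of the full
    rendered depth field (surface plus disc-plane imprint), expressed in the
    rendered frame so it is directly comparable with detector output.
    """
    zr_raster, offset = rendered_depth_um(surface, render, landmarks)
    del zr_raster
    extra = (
        (lambda X, Y: disc_plane_offset_um(X, Y, landmarks))
        if landmarks.tilt_deg > 0.0
        else None
    )
    x, y, z = surface.argmax_depth(extra_depth=extra)
    depth = z + offset
    torsion, ovality, h_tilt, v_tilt = _true_disc_config(landmarks)
    return EyeTruth(
        eye_id=eye_id,
        group=group,
        laterality=laterality,
        surface=surface,
        landmarks=landmarks,
        render=render,
        true_dpe_mm=(x, y),
        true_dpe_depth_um=depth,
        true_dpe_section=int(round(depth / render.section_pitch_um)),
        true_torsion_deg=torsion,
        true_ovality=ovality,
        true_h_tilt_deg=h_tilt,
        true_v_tilt_deg=v_tilt,
        covariates=dict(covariates or {}),
    )


# ---- cohort parameter distributions --------------------------------------


@dataclass(frozen=True)
class Dist:
    """Truncated normal (mean, sd, lo, hi); sd == 0 degenerates to the mean."""

    mean: float
    sd: float
    lo: float = -math.inf
    hi: float = math.inf

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0.0:
            return float(min(max(self.mean, self.lo), self.hi))
        for _ in range(1000):
            v = float(rng.normal(self.mean, self.sd))
            if self.lo <= v <= self.hi:
                return v
        raise RuntimeError(f"truncated-normal rejection failed for {self}")


@dataclass(frozen=True)
class GroupSpec:
    """Per-group anatomy and covariate distributions for cohort simulation.

    Category weights follow the printed myopic/emmetropic DPE-location
    distributions; axial length and spherical equivalent are truncated to the
    group-definition thresholds (AL > 24 mm & SE < -2 D vs AL < 24 mm &
    SE > 0.5 D) and eyes beyond 30 mm axial length are resampled.
    """

    name: str
    weight: float
    axial_length_mm: Dist
    se_diopter: Dist
    age_yr: Dist
    rnfl_um: Dist
    cct_um: Dist
    vf_md_db: Dist
    right_eye_fraction: float
    male_fraction: float
    category_weights: dict[str, float]
    bump_amplitude_um: Dist
    bump_sigma_mm: Dist
    base_radius_mm: Dist
    disc_offset_mm: Dist
    disc_radius_mm: Dist
    disc_fovea_angle_deg: Dist
    tilt_deg: Dist
    tilt_azimuth_jitter_sd_deg: float = 10.0
    amplitude_per_al_mm: float = 0.0  # extra um of bump per mm of AL above 24


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    render: RenderParams = field(default_factory=RenderParams)


def default_cohort_spec(render: RenderParams | None = None) -> CohortSpec:
    """Cohort defaults shaped like the published myopic/emmetropic series.

    Group weights 40:125, covariate means/SDs and DPE-location proportions
    from the printed baseline and comparison tables; bump amplitude and disc
    tilt magnitudes chosen so measured disc-DPE depths and tilt angles land
    in the printed ranges.
    """
    emmetropic = GroupSpec(
        name="emmetropic",
        weight=40.0 / 165.0,
        axial_length_mm=Dist(23.11, 0.62, 21.5, 23.99),
        se_diopter=Dist(0.24, 1.39, 0.51, 4.0),
        age_yr=Dist(59.75, 11.88, 20.0, 90.0),
        rnfl_um=Dist(102.32, 10.71, 60.0, 140.0),
        cct_um=Dist(534.6, 32.08, 420.0, 650.0),
        vf_md_db=Dist(-0.95, 1.85, -8.0, 3.0),
        right_eye_fraction=26.0 / 40.0,
        male_fraction=12.0 / 40.0,
        category_weights={
            "near_fovea": 0.225,
            "superior": 0.075,
            "inferior": 0.225,
            "near_disc": 0.475,
        },
        bump_amplitude_um=Dist(120.0, 50.0, 30.0, 300.0),
        bump_sigma_mm=Dist(1.7, 0.25, 1.3, 2.2),
        base_radius_mm=Dist(60.0, 8.0, 40.0, 90.0),
        disc_offset_mm=Dist(4.6, 0.25, 3.9, 5.3),
        disc_radius_mm=Dist(0.85, 0.07, 0.65, 1.05),
        disc_fovea_angle_deg=Dist(6.49, 3.59, 0.0, 14.0),
        tilt_deg=Dist(3.2, 4.0, 0.0, 14.0),
    )
    myopic = GroupSpec(
        name="myopic",
        weight=125.0 / 165.0,
        axial_length_mm=Dist(26.02, 1.33, 24.01, 30.0),
        se_diopter=Dist(-4.34, 3.54, -12.0, -2.01),
        age_yr=Dist(43.70, 11.96, 18.0, 80.0),
        rnfl_um=Dist(94.40, 14.09, 55.0, 135.0),
        cct_um=Dist(534.6, 45.24, 420.0, 650.0),
        vf_md_db=Dist(-1.45, 1.78, -8.0, 3.0),
        right_eye_fraction=55.0 / 125.0,
        male_fraction=51.0 / 125.0,
        category_weights={
            "near_fovea": 0.312,
            "superior": 0.056,
            "inferior": 0.432,
            "near_disc": 0.200,
        },
        bump_amplitude_um=Dist(250.0, 90.0, 40.0, 550.0),
        bump_sigma_mm=Dist(1.7, 0.25, 1.3, 2.2),
        base_radius_mm=Dist(60.0, 8.0, 40.0, 90.0),
        disc_offset_mm=Dist(4.6, 0.25, 3.9, 5.3),
        disc_radius_mm=Dist(0.85, 0.07, 0.65, 1.05),
        disc_fovea_angle_deg=Dist(7.36, 3.45, 0.0, 14.0),
        tilt_deg=Dist(11.0, 8.0, 0.0, 24.0),
        amplitude_per_al_mm=25.0,
    )
    return CohortSpec(groups=(emmetropic, myopic), render=render or RenderParams())


_CLASS_RADIUS_MM = 3.0  # 3000 um near-fovea / near-disc classification radius


def _sample_bump_center(
    rng: np.random.Generator, category: str, disc_center: np.ndarray
) -> tuple[float, float]:
    """Draw a bump center whose intended DPE category is ``category``.

    Positions are relative to the fovea at the origin; rejection sampling
    enforces the 3000-um near-fovea/near-disc radii, the fovea-disc
    half-plane split and a margin from the field edge.
    """
    fovea = np.zeros(2)
    t_hat = unit(fovea - disc_center)
    i_hat = inferior_normal(t_hat)
    lo_x, hi_x = FIELD_X_MM[0] + 1.0, FIELD_X_MM[1] - 1.0
    lo_y, hi_y = FIELD_Y_MM[0] + 0.8, FIELD_Y_MM[1] - 0.8
    for _ in range(10000):
        if category == "near_fovea":
            p = rng.normal([0.0, -0.3], 0.7)
            ok = np.hypot(*p) <= _CLASS_RADIUS_MM - 0.1
        elif category == "near_disc":
            p = disc_center + rng.normal([0.5, 0.0], 0.7)
            d_disc = float(np.hypot(*(p - disc_center)))
            # stay clear of the nerve head itself: a staphyloma apex on the
            # disc would ride the ONH-plane step rather than the globe wall
            ok = 1.5 <= d_disc <= _CLASS_RADIUS_MM - 0.1
        else:
            p = np.array([rng.uniform(lo_x, 1.5), rng.uniform(0.9, 4.2)])
            if category == "inferior":
                p[1] = -p[1]
            side = float(np.dot(p - fovea, i_hat))
            ok = (
                (side > 0.3 if category == "inferior" else side < -0.3)
                and np.hypot(*p) > _CLASS_RADIUS_MM + 0.1
                and float(np.hypot(*(p - disc_center))) > _CLASS_RADIUS_MM + 0.1
            )
        if ok and lo_x <= p[0] <= hi_x and lo_y <= p[1] <= hi_y:
            return float(p[0]), float(p[1])
    raise RuntimeError(f"could not place a bump for category {category!r}")


def _allocate_counts(weights: Sequence[float], n: int) -> list[int]:
    """Largest-remainder apportionment of n eyes over group weights."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = w * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    for k in range(rem):
        counts[order[k]] += 1
    return counts.tolist()


def _sample_eye_truth(
    spec: GroupSpec, render: RenderParams, eye_id: str, ss: np.random.SeedSequence
) -> EyeTruth:
    rng = np.random.default_rng(ss)
    n_resampled = 0
    while True:
        al = spec.axial_length_mm.sample(rng)
        if al > 30.0:  # exclusion rule; Dist truncation normally prevents this
            n_resampled += 1
            continue
        break
    if n_resampled:
        log.info("%s: resampled %d draws with axial length > 30 mm", eye_id, n_resampled)
    se = spec.se_diopter.sample(rng)
    covariates = {
        "age_yr": spec.age_yr.sample(rng),
        "se_diopter": se,
        "axial_length_mm": al,
        "rnfl_um": spec.rnfl_um.sample(rng),
        "cct_um": spec.cct_um.sample(rng),
        "vf_md_db": spec.vf_md_db.sample(rng),
        "sex": "male" if rng.random() < spec.male_fraction else "female",
    }
    laterality = "right" if rng.random() < spec.right_eye_fraction else "left"

    disc_offset = spec.disc_offset_mm.sample(rng)
    disc_radius = spec.disc_radius_mm.sample(rng)
    disc_fovea_angle = spec.disc_fovea_angle_deg.sample(rng)
    alpha = math.radians(disc_fovea_angle)
    disc_center = np.array([-disc_offset * math.cos(alpha), disc_offset * math.sin(alpha)])

    cats = sorted(spec.category_weights)
    probs = np.array([spec.category_weights[c] for c in cats], dtype=float)
    category = str(rng.choice(cats, p=probs / probs.sum()))
    bump_center = _sample_bump_center(rng, category, disc_center)
    amplitude = spec.bump_amplitude_um.sample(rng) + spec.amplitude_per_al_mm * max(
        al - 24.0, 0.0
    )
    sigma = spec.bump_sigma_mm.sample(rng)
    surface = SurfaceModel(
        base_radius_mm=spec.base_radius_mm.sample(rng),
        bump_center_mm=bump_center,
        bump_amplitude_um=amplitude,
        bump_sigma_mm=sigma,
        axial_length_mm=al,
    )

    tilt_deg = spec.tilt_deg.sample(rng)
    # the disc is pulled toward the DPE, and empirically tilt grows with the
    # disc-DPE depth; cap the tilt so the ONH-plane dip (~1000 r sin(tilt)),
    # plus the bump's own tail at the margin, stays below the bump peak and
    # the bump remains the deepest point of the eye
    gap = max(
        float(np.hypot(*(np.asarray(bump_center) - disc_center))) - disc_radius, 0.3
    )
    prominence = amplitude * (1.0 - math.exp(-(gap**2) / (2.0 * sigma**2)))
    max_dip = math.asin(min(0.95, 0.8 * prominence / (1000.0 * disc_radius)))
    tilt_deg = min(tilt_deg, math.degrees(max_dip))
    toward_dpe = signed_angle_deg(disc_center, bump_center)
    tilt = DiscTilt(
        downhill_azimuth_deg=toward_dpe + rng.normal(0.0, spec.tilt_azimuth_jitter_sd_deg),
        tilt_deg=tilt_deg,
    )
    landmarks = place_landmarks(
        surface,
        disc_offset_mm=disc_offset,
        disc_radius_mm=disc_radius,
        disc_fovea_angle_deg=disc_fovea_angle,
        tilt=tilt if tilt_deg > 0 else None,
        laterality="right",  # canonical; mirrored at scan time
    )
    return make_eye_truth(
        eye_id, spec.name, laterality, surface, landmarks, render, covariates
    )


def simulate_truths(spec: CohortSpec, n: int, seed: int | None) -> list[EyeTruth]:
    """Draw ``n`` ground-truth eyes (no rendering) from the cohort spec.

    For a given seed the truths equal those of :func:`simulate_cohort`.
    """
    if n < 1:
        raise PhantomParameterError("n must be >= 1")
    truth_seed, _ = np.random.SeedSequence(seed).spawn(2)
    return _simulate_truths_from_ss(spec, n, truth_seed)


def simulate_cohort(
    spec: CohortSpec, n: int, seed: int | None
) -> Iterator[SimulatedEye]:
    """Lazily simulate a cohort: yields (truth, volume, as-scanned landmarks).

    Volumes are rendered one at a time (a full-size stack is ~0.4 GB); left
    eyes are yielded in mirrored left-eye format, truths stay canonical.
    Reproducible for a fixed seed.
    """
    root = np.random.SeedSequence(seed)
    truth_seed, render_seed = root.spawn(2)
    truths = _simulate_truths_from_ss(spec, n, truth_seed)
    render_children = render_seed.spawn(n)
    for truth, rss in zip(truths, render_children):
        vol = render_enface(truth.surface, spec.render, seed=rss, landmarks=truth.landmarks)
        lm = truth.landmarks
        if truth.laterality == "left":
            vol, lm = mirror_volume(vol), mirror_landmarks(lm)
        yield SimulatedEye(truth=truth, volume=vol, scan_landmarks=lm)


def _simulate_truths_from_ss(
    spec: CohortSpec, n: int, ss: np.random.SeedSequence
) -> list[EyeTruth]:
    counts = _allocate_counts([g.weight for g in spec.groups], n)
    children = ss.spawn(n)
    truths: list[EyeTruth] = []
    i = 0
    for g, cnt in zip(spec.groups, counts):
        for _ in range(cnt):
            truths.append(_sample_eye_truth(g, spec.render, f"eye{i:03d}", children[i]))
            i += 1
    return truths


# --------------------------------------------------------------------------
# Re-scans
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RescanSpec:
    """Intervisit jitter: lateral fixation offset SD (mm); fresh speckle."""

    fixation_sd_mm: float = 0.05

    def __post_init__(self) -> None:
        if self.fixation_sd_mm < 0:
            raise PhantomParameterError("fixation_sd_mm must be >= 0")


@dataclass(frozen=True)
class RescanResult:
    volume: EnFaceVolume
    landmarks: Landmarks
    offset_mm: tuple[float, float]


def rescan(
    truth: EyeTruth,
    jitter: RescanSpec | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> RescanResult:
    """Re-image the same anatomy on another visit.

    Applies an independent speckle realization and, when ``fixation_sd_mm``
    is nonzero, a lateral fixation offset that translates the whole anatomy
    (and the scanner-reported landmarks) relative to the fixed scan raster.
    With zero jitter and zero speckle the volume is identical to the
    original.
    """
    jitter = jitter or RescanSpec()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    offset_ss, speckle_ss = ss.spawn(2)
    if jitter.fixation_sd_mm > 0:
        d = np.random.default_rng(offset_ss).normal(0.0, jitter.fixation_sd_mm, 2)
    else:
        d = np.zeros(2)
    surface = replace(
        truth.surface,
        bump_center_mm=(truth.surface.bump_center_mm[0] + d[0],
                        truth.surface.bump_center_mm[1] + d[1]),
        base_center_mm=(truth.surface.base_center_mm[0] + d[0],
                        truth.surface.base_center_mm[1] + d[1]),
    )
    lm = truth.landmarks
    margin = lm.disc_margin.copy()
    margin[:, 0] += d[0]
    margin[:, 1] += d[1]
    lm = replace(
        lm,
        fovea_mm=(lm.fovea_mm[0] + d[0], lm.fovea_mm[1] + d[1]),
        disc_center_mm=(lm.disc_center_mm[0] + d[0], lm.disc_center_mm[1] + d[1]),
        disc_margin=margin,
    )
    vol = render_enface(surface, truth.render, seed=speckle_ss, landmarks=lm)
    if truth.laterality == "left":
        vol, lm = mirror_volume(vol), mirror_landmarks(lm)
    return RescanResult(volume=vol, landmarks=lm, offset_mm=(float(d[0]), float(d[1])))
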