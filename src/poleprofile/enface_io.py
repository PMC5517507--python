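"""Volume, landmark and result-table I/O.

Volumes travel as a multi-page 16-bit grayscale TIFF (one page per coronal
section, anterior to posterior) plus a JSON sidecar carrying the geometry
(lateral pitch, section pitch, origin, laterality), the landmarks and,
optionally, the ground-truth block.  Cohort tables are RFC-4180 CSV with a
leading ``#``-comment line recording the schema version and per-column
units ('.' decimal separator; values round-trip bit-exactly through the
shortest-repr float formatting).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic_eye import EnFaceVolume, Landmarks

__all__ = [
    "FormatError",
    "LoadedVolume",
    "write_volume",
    "read_volume",
    "COHORT_SCHEMA",
    "CohortTable",
    "write_table",
    "read_table",
]


class FormatError(ValueError):
    """Malformed volume pair or cohort table."""


# --------------------------------------------------------------------------
# Volumes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LoadedVolume:
    """A volume with its sidecar landmarks and optional truth block."""

    volume: EnFaceVolume
    landmarks: Landmarks | None
    truth: dict | None


def _landmarks_to_json(lm: Landmarks) -> dict:
    return {
        "fovea_mm": list(lm.fovea_mm),
        "disc_center_mm": list(lm.disc_center_mm),
        "disc_radius_mm": lm.disc_radius_mm,
        "disc_margin": np.asarray(lm.disc_margin).tolist(),
        "tilt_downhill": list(lm.tilt_downhill),
        "tilt_deg": lm.tilt_deg,
        "laterality": lm.laterality,
    }


def _landmarks_from_json(d: dict) -> Landmarks:
    try:
        return Landmarks(
            fovea_mm=tuple(d["fovea_mm"]),
            disc_center_mm=tuple(d["disc_center_mm"]),
            disc_radius_mm=float(d["disc_radius_mm"]),
            disc_margin=np.asarray(d["disc_margin"], dtype=float),
            tilt_downhill=tuple(d["tilt_downhill"]),
            tilt_deg=float(d["tilt_deg"]),
            laterality=d["laterality"],
        )
    except KeyError as exc:
        raise FormatError(f"sidecar landmarks block missing field {exc}") from exc


def write_volume(
    volume: EnFaceVolume,
    path: str | Path,
    landmarks: Landmarks | None = None,
    truth: dict | None = None,
) -> tuple[Path, Path]:
    """Write ``<path>.tif`` + ``<path>.json``; returns the two paths."""
    base = Path(path)
    tif_path = base.with_suffix(".tif")
    json_path = base.with_suffix(".json")
    data = np.asarray(volume.intensities)
    if data.dtype != np.uint16:
        raise FormatError(f"volume intensities must be uint16, got {data.dtype}")
    sidecar = {
        "format": "poleprofile-enface v1",
        "lateral_pitch_mm": volume.lateral_pitch_mm,
        "section_pitch_um": volume.section_pitch_um,
        "n_sections": volume.n_sections,
        "origin_mm": list(volume.origin_mm),
        "laterality": volume.laterality,
    }
    if landmarks is not None:
        sidecar["landmarks"] = _landmarks_to_json(landmarks)
    if truth is not None:
        sidecar["truth"] = truth
    tifffile.imwrite(tif_path, data, photometric="minisblack")
    json_path.write_text(json.dumps(sidecar, indent=1))
    return tif_path, json_path


def read_volume(path: str | Path) -> LoadedVolume:
    """Read a TIFF + sidecar pair written by :func:`write_volume`.

    Raises :class:`FormatError` for a missing sidecar, non-positive pitches
    or a page count that disagrees with the sidecar's ``n_sections``.
    """
    base = Path(path)
    tif_path = base.with_suffix(".tif")
    json_path = base.with_suffix(".json")
    if not json_path.exists():
        raise FormatError(f"missing sidecar {json_path}")
    if not tif_path.exists():
        raise FormatError(f"missing volume {tif_path}")
    sidecar = json.loads(json_path.read_text())
    for key in ("lateral_pitch_mm", "section_pitch_um", "n_sections", "origin_mm", "laterality"):
        if key not in sidecar:
            raise FormatError(f"sidecar missing field {key!r}")
    if sidecar["lateral_pitch_mm"] <= 0:
        raise FormatError("lateral_pitch_mm must be > 0")
    if sidecar["section_pitch_um"] <= 0:
        raise FormatError("section_pitch_um must be > 0")
    data = tifffile.imread(tif_path)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != int(sidecar["n_sections"]):
        raise FormatError(
            f"n_sections={sidecar['n_sections']} in sidecar but {data.shape[0]} TIFF pages"
        )
    volume = EnFaceVolume(
        intensities=data,
        lateral_pitch_mm=float(sidecar["lateral_pitch_mm"]),
        section_pitch_um=float(sidecar["section_pitch_um"]),
        origin_mm=tuple(sidecar["origin_mm"]),
        laterality=sidecar["laterality"],
    )
    landmarks = (
        _landmarks_from_json(sidecar["landmarks"]) if "landmarks" in sidecar else None
    )
    return LoadedVolume(volume=volume, landmarks=landmarks, truth=sidecar.get("truth"))


# --------------------------------------------------------------------------
# Cohort tables
# --------------------------------------------------------------------------

_SCHEMA_VERSION = "poleprofile-cohort v1"

#: Column -> unit ('' for dimensionless / labels).  Fixed, versioned schema.
COHORT_SCHEMA: dict[str, str] = {
    "eye_id": "",
    "group": "",
    "laterality": "",
    "sex": "",
    "age_yr": "yr",
    "se_diopter": "D",
    "axial_length_mm": "mm",
    "rnfl_um": "um",
    "cct_um": "um",
    "vf_md_db": "dB",
    "dpe_section": "count",
    "dpe_x_mm": "mm",
    "dpe_y_mm": "mm",
    "dpe_depth_um": "um",
    "dpe_area_mm2": "mm2",
    "dpe_quality": "",
    "disc_dpe_distance_um": "um",
    "fovea_dpe_distance_um": "um",
    "disc_dpe_depth_um": "um",
    "fovea_dpe_depth_um": "um",
    "disc_dpe_angle_deg": "deg",
    "disc_fovea_angle_deg": "deg",
    "torsion_deg": "deg",
    "torsion_defined": "",
    "ovality": "",
    "long_axis_um": "um",
    "short_axis_um": "um",
    "h_tilt_deg": "deg",
    "v_tilt_deg": "deg",
    "dpe_category": "",
    "true_dpe_x_mm": "mm",
    "true_dpe_y_mm": "mm",
    "true_dpe_depth_um": "um",
    "true_dpe_section": "count",
    "true_torsion_deg": "deg",
    "true_ovality": "",
    "true_h_tilt_deg": "deg",
    "true_v_tilt_deg": "deg",
    "true_bump_amplitude_um": "um",
}


@dataclass(frozen=True)
class CohortTable:
    """One row per eye; columns restricted to :data:`COHORT_SCHEMA`."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        unknown = [c for c in self.data.columns if c not in COHORT_SCHEMA]
        if unknown:
            raise FormatError(f"unknown cohort column(s): {', '.join(unknown)}")

    def summary(self, variables: list[str], by: str = "group") -> pd.DataFrame:
        from .stats_layer import summarize_mean_sd

        return summarize_mean_sd(self.data, variables, by=by)


def write_table(table: CohortTable | pd.DataFrame, path: str | Path) -> Path:
    """Write a cohort CSV with the version/units comment line."""
    if isinstance(table, pd.DataFrame):
        table = CohortTable(table)
    path = Path(path)
    units = ",".join(f"{c}={COHORT_SCHEMA[c]}" for c in table.data.columns)
    header = f"# {_SCHEMA_VERSION}; units: {units}\n"
    csv = table.data.to_csv(index=False, lineterminator="\n")
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(header + csv)
    tmp.replace(path)  # never leave a partial table behind
    return path


def read_table(path: str | Path) -> CohortTable:
    """Read a cohort CSV written by :func:`write_table` (schema-checked)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(f"# {_SCHEMA_VERSION}"):
            raise FormatError(f"{path} is not a {_SCHEMA_VERSION} table")
        # round_trip parsing: the default fast parser is off by 1 ulp on some
        # values, breaking bit-exact round-trips
        data = pd.read_csv(fh, float_precision="round_trip")
    return CohortTable(data)
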