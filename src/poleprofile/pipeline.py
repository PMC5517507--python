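"""End-to-end orchestration: simulate, detect, measure, classify, analyse.

``run_pipeline`` drives a full synthetic study: cohort simulation, DPE
detection and disc measurement per eye, four-region classification, and the
statistics layer, emitting the cohort CSV plus analogues of the published
tables (baseline comparison, DPE-property comparison, by-category
comparison, correlations, regressions, reproducibility ICC).  Every
stochastic stage derives from the single configured seed; the same config
produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .disc_config import measure_disc
from .dpe_detection import SegParams, depth_map, locate_dpe
from .enface_io import COHORT_SCHEMA, CohortTable, write_table, write_volume
from .geometry_model import classify_dpe
from .pole_metrics import posterior_pole_metrics
from .stats_layer import (
    compare_groups,
    correlation_matrix,
    icc_two_way_mixed,
    regression_tables,
    summarize_mean_sd,
)
from .synthetic_eye import (
    CohortSpec,
    RenderParams,
    RescanSpec,
    default_cohort_spec,
    rescan,
    simulate_cohort,
    simulate_truths,
    to_right_format,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "measure_eye", "run_pipeline", "reproducibility_run"]

ALL_TABLES = (
    "cohort",
    "baseline",
    "dpe_comparison",
    "by_category",
    "correlations",
    "regressions",
    "reproducibility",
)

_DPE_METRIC_COLS = [
    "disc_dpe_distance_um",
    "fovea_dpe_distance_um",
    "disc_dpe_depth_um",
    "fovea_dpe_depth_um",
    "disc_dpe_angle_deg",
    "disc_fovea_angle_deg",
    "torsion_deg",
    "ovality",
    "h_tilt_deg",
    "v_tilt_deg",
]

_REGRESSION_CANDIDATES = [
    "disc_dpe_distance_um",
    "fovea_dpe_distance_um",
    "disc_dpe_depth_um",
    "fovea_dpe_depth_um",
    "disc_dpe_angle_deg",
]

#: Table-1 reproducibility metrics (column name -> measured-row key).
REPRO_METRICS = (
    "dpe_section",
    "disc_dpe_distance_um",
    "disc_dpe_depth_um",
    "fovea_dpe_depth_um",
    "disc_dpe_angle_deg",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; message carries the eye id and stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline run configuration (round-trips through YAML/JSON).

    ``render`` controls the raster/axial problem size and speckle level;
    ``jitter_sd_mm`` the intervisit fixation offset; ``repro_n_*`` the
    reproducibility design (default 10 emmetropic + 15 myopic series
    scanned twice).
    """

    n_eyes: int = 165
    seed: int = 0
    out_dir: str = "poleprofile_out"
    render: RenderParams = field(default_factory=RenderParams)
    seg: SegParams = field(default_factory=SegParams)
    jitter_sd_mm: float = 0.05
    repro_n_emmetropic: int = 10
    repro_n_myopic: int = 15
    save_volumes: bool = False
    tables: tuple[str, ...] = ALL_TABLES

    def __post_init__(self) -> None:
        unknown = set(self.tables) - set(ALL_TABLES)
        if unknown:
            raise ValueError(f"unknown table selection(s): {sorted(unknown)}")
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tables"] = list(self.tables)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "render" in d and isinstance(d["render"], dict):
            d["render"] = RenderParams(**d["render"])
        if "seg" in d and isinstance(d["seg"], dict):
            d["seg"] = SegParams(**d["seg"])
        if "tables" in d:
            d["tables"] = tuple(d["tables"])
        return cls(**d)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def measure_eye(volume, landmarks, seg: SegParams | None = None) -> dict:
    """Detect and measure one scan; returns the measured cohort-row fields.

    Left-format scans are mirrored to the canonical right-eye frame first.
    """
    vol, lm = to_right_format(volume, landmarks)
    dm = depth_map(vol, seg)
    dpe = locate_dpe(vol, seg, depth=dm)
    metrics = posterior_pole_metrics(dpe, lm, dm)
    disc = measure_disc(lm, dm)
    category = classify_dpe(dpe.center_mm, lm)
    return {
        "dpe_section": dpe.section_index,
        "dpe_x_mm": dpe.center_mm[0],
        "dpe_y_mm": dpe.center_mm[1],
        "dpe_depth_um": dpe.depth_um,
        "dpe_area_mm2": dpe.region_area_mm2,
        "dpe_quality": "|".join(sorted(dpe.quality)) or "ok",
        "disc_dpe_distance_um": metrics.disc_dpe_distance_um,
        "fovea_dpe_distance_um": metrics.fovea_dpe_distance_um,
        "disc_dpe_depth_um": metrics.disc_dpe_depth_um,
        "fovea_dpe_depth_um": metrics.fovea_dpe_depth_um,
        "disc_dpe_angle_deg": metrics.disc_dpe_angle_deg,
        "disc_fovea_angle_deg": metrics.disc_fovea_angle_deg,
        "torsion_deg": disc.torsion_deg,
        "torsion_defined": disc.torsion_defined,
        "ovality": disc.ovality,
        "long_axis_um": disc.long_axis_um,
        "short_axis_um": disc.short_axis_um,
        "h_tilt_deg": disc.h_tilt_deg,
        "v_tilt_deg": disc.v_tilt_deg,
        "dpe_category": category.label,
    }


def build_cohort_table(config: PipelineConfig, spec: CohortSpec | None = None) -> CohortTable:
    """Simulate, detect and measure the whole cohort (in-memory volumes)."""
    spec = spec or default_cohort_spec(config.render)
    rows = []
    out = Path(config.out_dir)
    for sim in simulate_cohort(spec, config.n_eyes, config.seed):
        truth = sim.truth
        try:
            measured = measure_eye(sim.volume, sim.scan_landmarks, config.seg)
        except Exception as exc:
            raise PipelineError(
                f"eye {truth.eye_id}: detection/measurement stage failed: {exc}"
            ) from exc
        row = {
            "eye_id": truth.eye_id,
            "group": truth.group,
            "laterality": truth.laterality,
            "sex": truth.covariates.get("sex", ""),
            "age_yr": truth.covariates.get("age_yr", math.nan),
            "se_diopter": truth.covariates.get("se_diopter", math.nan),
            "axial_length_mm": truth.covariates.get("axial_length_mm", math.nan),
            "rnfl_um": truth.covariates.get("rnfl_um", math.nan),
            "cct_um": truth.covariates.get("cct_um", math.nan),
            "vf_md_db": truth.covariates.get("vf_md_db", math.nan),
            **measured,
            "true_dpe_x_mm": truth.true_dpe_mm[0],
            "true_dpe_y_mm": truth.true_dpe_mm[1],
            "true_dpe_depth_um": truth.true_dpe_depth_um,
            "true_dpe_section": truth.true_dpe_section,
            "true_torsion_deg": truth.true_torsion_deg,
            "true_ovality": truth.true_ovality,
            "true_h_tilt_deg": truth.true_h_tilt_deg,
            "true_v_tilt_deg": truth.true_v_tilt_deg,
            "true_bump_amplitude_um": truth.surface.bump_amplitude_um,
        }
        rows.append(row)
        if config.save_volumes:
            out.mkdir(parents=True, exist_ok=True)
            write_volume(sim.volume, out / "volumes" / truth.eye_id, sim.scan_landmarks)
        log.info("measured %s (%s, %s)", truth.eye_id, truth.group, row["dpe_category"])
    df = pd.DataFrame(rows)[list(COHORT_SCHEMA)]
    return CohortTable(df)


# --------------------------------------------------------------------------
# Statistics tables
# --------------------------------------------------------------------------


def _safe_compare(df: pd.DataFrame, grouping: str, continuous, categorical):
    """Group comparison that degrades to mean +- SD summaries when a group is
    too small for the tests (smoke-scale cohorts)."""
    counts = df[grouping].value_counts()
    if len(counts) >= 2 and counts.min() >= 2:
        return compare_groups(df, grouping, continuous=continuous, categorical=categorical)
    summary = summarize_mean_sd(df, continuous, by=grouping).reset_index(names="variable")
    summary.insert(1, "note", "groups too small for inferential tests")
    return summary


_REGRESSION_COLS = [
    "subset", "dependent", "analysis", "variable", "beta", "ci_low", "ci_high",
    "p_value", "note",
]


def _regression_table(df: pd.DataFrame, label: str) -> pd.DataFrame:
    """Torsion and ovality regressions for one subset, long-form."""
    rows: list[dict] = []
    for dependent in ("torsion_deg", "ovality"):
        candidates = [c for c in _REGRESSION_CANDIDATES if c != dependent]
        max_cand = max(1, len(df) - 4)
        candidates = candidates[:max_cand]
        try:
            report = regression_tables(df, dependent, candidates)
        except ValueError as exc:
            rows.append({"subset": label, "dependent": dependent, "note": str(exc)})
            continue
        for analysis, frame in (
            ("univariate", report.univariate),
            ("multivariate", report.multivariate),
        ):
            for rec in frame.to_dict("records"):
                rows.append(
                    {"subset": label, "dependent": dependent, "analysis": analysis, **rec}
                )
    return pd.DataFrame(rows, columns=_REGRESSION_COLS)


def analysis_tables(table: CohortTable, config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Build the requested statistics tables from a measured cohort."""
    df = table.data
    out: dict[str, pd.DataFrame] = {}
    if "baseline" in config.tables:
        out["baseline"] = _safe_compare(
            df,
            "group",
            continuous=["age_yr", "se_diopter", "axial_length_mm", "cct_um", "vf_md_db", "rnfl_um"],
            categorical=["laterality", "sex"],
        )
    if "dpe_comparison" in config.tables:
        out["dpe_comparison"] = _safe_compare(
            df, "group", continuous=_DPE_METRIC_COLS, categorical=["dpe_category"]
        )
    if "by_category" in config.tables:
        myopic = df[df.group == "myopic"]
        cat_counts = myopic["dpe_category"].value_counts()
        usable = myopic[myopic.dpe_category.isin(cat_counts[cat_counts >= 2].index)]
        cols = ["age_yr", "se_diopter", "axial_length_mm", "vf_md_db", "rnfl_um"] + _DPE_METRIC_COLS
        if usable["dpe_category"].nunique() >= 2:
            out["by_category"] = _safe_compare(usable, "dpe_category", cols, [])
        else:
            out["by_category"] = summarize_mean_sd(myopic, cols, by="dpe_category").reset_index(
                names="variable"
            )
    if "correlations" in config.tables:
        out["correlations"] = correlation_matrix(
            df,
            ["age_yr", "se_diopter", "axial_length_mm", "vf_md_db", "rnfl_um"]
            + _DPE_METRIC_COLS,
        )
    if "regressions" in config.tables:
        frames = [_regression_table(df, "all")]
        for name, sub in df.groupby("group", observed=True):
            frames.append(_regression_table(sub, str(name)))
        out["regressions"] = pd.concat(frames, ignore_index=True)[_REGRESSION_COLS]
    return out


# --------------------------------------------------------------------------
# Reproducibility (Table 1 analogue)
# --------------------------------------------------------------------------


def reproducibility_run(
    config: PipelineConfig, spec: CohortSpec | None = None
) -> pd.DataFrame:
    """Intervisit ICC over simulated re-scan pairs.

    Simulates ``repro_n_emmetropic + repro_n_myopic`` eyes (default
    10 + 15 = 25 independent series), scans each twice with fresh speckle
    and the configured fixation jitter, measures the five reproducibility
    metrics per visit and returns single/average-measure ICCs with 95% CIs.
    """
    m = config.repro_n_emmetropic + config.repro_n_myopic
    if m < 3:
        raise ValueError("need at least 3 reproducibility series")
    base = spec or default_cohort_spec(config.render)
    groups = []
    for g in base.groups:
        n_g = config.repro_n_emmetropic if g.name == "emmetropic" else config.repro_n_myopic
        groups.append(replace(g, weight=float(n_g)))
    spec = replace(base, groups=tuple(groups))

    truths = simulate_truths(spec, m, config.seed + 1)
    jitter = RescanSpec(fixation_sd_mm=config.jitter_sd_mm)
    visits: dict[str, list[list[float]]] = {k: [[], []] for k in REPRO_METRICS}
    ss = np.random.SeedSequence(config.seed + 2).spawn(2 * m)
    for i, truth in enumerate(truths):
        for visit in (0, 1):
            scan = rescan(truth, jitter, seed=ss[2 * i + visit])
            try:
                row = measure_eye(scan.volume, scan.landmarks, config.seg)
            except Exception as exc:
                raise PipelineError(
                    f"eye {truth.eye_id}: reproducibility visit {visit + 1} failed: {exc}"
                ) from exc
            for k in REPRO_METRICS:
                visits[k][visit].append(float(row[k]))
    records = []
    for k in REPRO_METRICS:
        ratings = np.column_stack([visits[k][0], visits[k][1]])
        icc = icc_two_way_mixed(ratings)
        records.append(
            {
                "metric": k,
                "icc_single": icc.icc_single,
                "icc_single_ci_low": icc.ci95_single[0],
                "icc_single_ci_high": icc.ci95_single[1],
                "icc_average": icc.icc_average,
                "icc_average_ci_low": icc.ci95_average[0],
                "icc_average_ci_high": icc.ci95_average[1],
                "n_series": icc.n_subjects,
                "k_visits": icc.k_raters,
            }
        )
    return pd.DataFrame(records)


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, spec: CohortSpec | None = None) -> dict[str, Path]:
    """Run the full study and write all requested tables under ``out_dir``.

    Deterministic given the config seed.  On any stage failure the partial
    outputs written by this run are removed and a :class:`PipelineError`
    naming the eye and stage is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    paths: dict[str, Path] = {}
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("poleprofile")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    try:
        log.info("poleprofile %s; seed=%d; n_eyes=%d", __version__, config.seed, config.n_eyes)
        log.info("config: %s", json.dumps(config.to_dict(), sort_keys=True))
        table = build_cohort_table(config, spec)
        if "cohort" in config.tables:
            p = out / "cohort.csv"
            write_table(table, p)
            written.append(p)
            paths["cohort"] = p
        for name, frame in analysis_tables(table, config).items():
            p = out / f"table_{name}.csv"
            frame.to_csv(p, index=False, lineterminator="\n")
            written.append(p)
            paths[name] = p
        if "reproducibility" in config.tables:
            p = out / "table_reproducibility.csv"
            reproducibility_run(config, spec).to_csv(p, index=False, lineterminator="\n")
            written.append(p)
            paths["reproducibility"] = p
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
        root.setLevel(old_level)
    paths["log"] = out / "run.log"
    return paths
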