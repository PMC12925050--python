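"""File formats and the end-to-end pipeline driver.

Everything on disk is plain text or TIFF: geometry and planning-tip
descriptors are JSON, segmentations and trajectories are CSV with fixed
headers and units in the column names, configuration is YAML. The
driver chains segment -> filter -> fit -> estimate -> evaluate and
writes every intermediate artifact so any stage can be re-run from its
CSV inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import (
    TrajectoryEstimate,
    estimate_3d,
    fit_gaussian_ml,
    negative_log_likelihood,
    observations_from_ground_truth,
    observations_from_segmentations,
)
from .filtering import filter_scan
from .geometry import BeamGeometry, ProjectionMeta, load_geometry
from .metrics import displacement_summary, estimation_errors, segmentation_success
from .phantom import LeadTipModel, read_stack
from .segmentation import Segmentation2D, segment_scan

__all__ = [
    "RunConfig",
    "load_planning_tip",
    "read_segmentations",
    "write_segmentations",
    "read_trajectory",
    "write_trajectory",
    "read_ground_truth",
    "run_pipeline",
]

log = logging.getLogger("leadtrack")

SEG_COLUMNS = ["index", "gantry_deg", "col_px", "row_px", "ncc", "rot_deg", "scale", "accepted"]
TRAJ_COLUMNS = ["index", "gantry_deg", "lr_mm", "si_mm", "ap_mm", "source"]
TRUTH_COLUMNS = ["index", "time_s", "gantry_deg", "lr_mm", "si_mm", "ap_mm", "u_px", "v_px"]


def load_planning_tip(path, contrast: float = 1.0) -> LeadTipModel:
    """Read the planning-tip JSON descriptor into a LeadTipModel."""
    with open(path) as fh:
        data = json.load(fh)
    missing = [k for k in ("position_mm", "axis", "radius_mm", "length_mm") if k not in data]
    if missing:
        raise KeyError(f"planning tip {path} is missing key(s): {', '.join(missing)}")
    axis = np.asarray(data["axis"], dtype=float)
    axis = axis / np.linalg.norm(axis)
    return LeadTipModel(
        radius=float(data["radius_mm"]),
        length=float(data["length_mm"]),
        axis=tuple(axis),
        contrast=contrast,
        planning_position=tuple(float(x) for x in data["position_mm"]),
    )


def _check_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def read_ground_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, TRUTH_COLUMNS, path)
    return df


def write_segmentations(path, segs: list[Segmentation2D], metas: list[ProjectionMeta]) -> None:
    angle_of = {m.index: m.gantry_angle for m in metas}
    lines = [",".join(SEG_COLUMNS)]
    for s in segs:
        lines.append(
            f"{s.projection_index},{angle_of[s.projection_index]:.6f},"
            f"{s.centroid[0]:.6f},{s.centroid[1]:.6f},{s.ncc_score:.6f},"
            f"{s.rotation_offset:.1f},{s.scale:.2f},{int(s.accepted)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_segmentations(path) -> tuple[list[Segmentation2D], list[ProjectionMeta]]:
    df = pd.read_csv(path)
    _check_columns(df, SEG_COLUMNS, path)
    segs, metas = [], []
    for _, r in df.iterrows():
        segs.append(
            Segmentation2D(
                projection_index=int(r["index"]),
                centroid=(float(r["col_px"]), float(r["row_px"])),
                ncc_score=float(r["ncc"]),
                rotation_offset=float(r["rot_deg"]),
                scale=float(r["scale"]),
                accepted=bool(r["accepted"]),
            )
        )
        metas.append(
            ProjectionMeta(index=int(r["index"]), gantry_angle=float(r["gantry_deg"]), time=0.0)
        )
    return segs, metas


def write_trajectory(path, traj: TrajectoryEstimate) -> None:
    lines = [",".join(TRAJ_COLUMNS)]
    for i in range(len(traj)):
        p = traj.positions[i]
        lines.append(
            f"{traj.indices[i]},{traj.gantry_angles[i]:.6f},"
            f"{p[0]:.6f},{p[1]:.6f},{p[2]:.6f},{traj.source}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory(path) -> TrajectoryEstimate:
    df = pd.read_csv(path)
    _check_columns(df, TRAJ_COLUMNS, path)
    return TrajectoryEstimate(
        indices=df["index"].to_numpy(),
        gantry_angles=df["gantry_deg"].to_numpy(),
        positions=df[["lr_mm", "si_mm", "ap_mm"]].to_numpy(),
        source=str(df["source"].iloc[0]) if len(df) else "filtered",
    )


def load_projection_stack(path, metas: list[ProjectionMeta]) -> np.ndarray:
    stack = read_stack(path)
    if len(stack) != len(metas):
        raise ValueError(
            f"projection stack {path} has {len(stack)} frames but the geometry "
            f"descriptor lists {len(metas)} gantry angles"
        )
    return stack


@dataclass
class RunConfig:
    """Paths and settings for an end-to-end tracking run."""

    projections: Path
    geometry: Path
    planning_tip: Path
    outdir: Path
    mode: str = "FB"
    ground_truth: Path | None = None  # enables evaluation against truth
    filter_threshold_px: float = 25.0
    warmup: int = 10
    meas_var: float = 0.25
    refine_passes: int = 1
    min_ncc: float | None = None
    with_raw: bool = True  # also produce the unfiltered-variant trajectory
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("projections", "geometry", "planning_tip"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        self.outdir = Path(self.outdir)
        if self.mode not in ("DIBH", "FB", "AC", "HFV"):
            raise ValueError(f"mode must be DIBH|FB|AC|HFV, got {self.mode!r}")


def _estimate_from_segs(segs, geom, metas, cfg: RunConfig, source: str) -> TrajectoryEstimate:
    obs = observations_from_segmentations(segs, geom, metas)
    if not obs:
        raise ValueError(f"no accepted segmentations to estimate from ({source})")
    params = fit_gaussian_ml(obs, meas_var=cfg.meas_var)
    skipped = tuple(s.projection_index for s in segs if not s.accepted)
    traj = estimate_3d(
        params, obs, geom=geom, refine_passes=cfg.refine_passes,
        source=source, skipped_indices=skipped,
    )
    log.info(
        "%s fit: mu=(%.2f, %.2f, %.2f) mm, nll=%.1f over %d obs",
        source, *params.mu, negative_log_likelihood(params, obs), len(obs),
    )
    return traj


def run_pipeline(cfg: RunConfig) -> dict:
    """Segment -> filter -> fit -> estimate -> evaluate one scan.

    Writes segmentations and trajectory CSVs plus a JSON report under
    ``cfg.outdir`` and returns the report dict.
    """
    t0 = _time.perf_counter()
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    geom, metas = load_geometry(cfg.geometry)
    lead = load_planning_tip(cfg.planning_tip)
    stack = load_projection_stack(cfg.projections, metas)

    log.info("segmenting %d projections (mode %s)", len(stack), cfg.mode)
    segs = segment_scan(stack, geom, metas, lead, cfg.mode, min_ncc=cfg.min_ncc, log=log)
    filtered, rejection_rate = filter_scan(
        segs, threshold=cfg.filter_threshold_px, warmup=cfg.warmup
    )
    log.info("filter rejected %.1f%% of segmentations", 100 * rejection_rate)
    write_segmentations(cfg.outdir / "segmentations.csv", filtered, metas)

    report: dict = {
        "n_projections": len(stack),
        "mode": cfg.mode,
        "rejection_rate": rejection_rate,
    }

    traj_filtered = _estimate_from_segs(filtered, geom, metas, cfg, "filtered")
    write_trajectory(cfg.outdir / "trajectory_filtered.csv", traj_filtered)
    if cfg.with_raw:
        raw = [s if s.accepted else dataclasses.replace(s, accepted=True) for s in segs]
        traj_raw = _estimate_from_segs(raw, geom, metas, cfg, "raw")
        write_trajectory(cfg.outdir / "trajectory_raw.csv", traj_raw)

    if cfg.ground_truth is not None:
        truth = read_ground_truth(cfg.ground_truth)
        truth_px = {
            int(i): (float(u), float(v))
            for i, u, v in zip(truth["index"], truth["u_px"], truth["v_px"])
        }
        seg_acc = segmentation_success(filtered, truth_px, geom.pixel_spacing)
        report["segmentation"] = {
            "fraction_success": seg_acc.fraction_success,
            "n_evaluated": seg_acc.n_evaluated,
        }
        obs_truth = observations_from_ground_truth(truth, geom)
        params_truth = fit_gaussian_ml(obs_truth, meas_var=cfg.meas_var)
        traj_truth = estimate_3d(
            params_truth, obs_truth, geom=geom, refine_passes=cfg.refine_passes, source="truth"
        )
        write_trajectory(cfg.outdir / "trajectory_truth.csv", traj_truth)
        disp = displacement_summary(traj_truth)
        report["displacement_mm"] = {ax: list(v) for ax, v in disp.per_axis.items()}
        acc = estimation_errors(traj_filtered, traj_truth)
        report["estimation_filtered"] = {
            "fraction_lt2mm": acc.fraction_success,
            "per_axis_percentiles": {ax: list(v) for ax, v in acc.per_axis_percentiles.items()},
        }
        if cfg.with_raw:
            acc_raw = estimation_errors(traj_raw, traj_truth)
            report["estimation_raw"] = {
                "fraction_lt2mm": acc_raw.fraction_success,
                "per_axis_percentiles": {
                    ax: list(v) for ax, v in acc_raw.per_axis_percentiles.items()
                },
            }

    report["elapsed_s"] = _time.perf_counter() - t0
    (cfg.outdir / "report.json").write_text(json.dumps(report, indent=1))
    log.info("pipeline finished in %.1f s", report["elapsed_s"])
    return report
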