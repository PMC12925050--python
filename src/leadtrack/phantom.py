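"""Digital phantom: simulated lead-tip motion and rendered kV projections.

The phantom stands in for patient CBCT scans. It simulates a 3D
trajectory of the ICD lead tip under a chosen motion-management regime
(deep inspiratory breath-hold, free breathing, abdominal compression or
high-frequency ventilation), renders the tip as a cylinder in every kV
projection, and writes a complete dataset (projection stack, geometry
descriptor, planning-tip descriptor, ground-truth trajectory) so the
tracking pipeline can be exercised against exact ground truth.

Respiratory motion for free breathing and abdominal compression uses the
cos^4 waveform standard in the radiotherapy motion literature (long
end-exhale dwell); breath-hold residual motion is a slow low-amplitude
sinusoid and high-frequency ventilation a fast small sinusoid. Cardiac
motion is a single sinusoid at the heart rate. Rendering uses a
parallel-beam approximation at the nominal magnification within the small
footprint of the tip, which is accurate to well below a pixel for a
~10 mm object at a 1000 mm source-axis distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

from .geometry import (
    BeamGeometry,
    ProjectionMeta,
    beam_frame,
    imager_mm_to_px,
    project_point,
    save_geometry,
)

__all__ = [
    "MotionModel",
    "LeadTipModel",
    "Trajectory3D",
    "simulate_trajectory",
    "render_projection",
    "generate_dataset",
    "default_metas",
    "write_stack",
    "read_stack",
    "MODES",
]

MODES = ("DIBH", "FB", "AC", "HFV")


@dataclass(frozen=True)
class MotionModel:
    """Parametric cardiorespiratory motion of the lead tip.

    Position at time t (mm, room frame lr/si/ap):

        baseline + drift*t + resp_amplitude * resp_wave(t)
                 + cardiac_amplitude * sin(2*pi*rate/60*t + phase)

    ``resp_wave`` depends on the regime: cos^4 (range [0, 1], end-exhale
    dwell) for FB and AC, a slow sinusoid for the residual motion under
    DIBH, and a fast sinusoid for HFV.
    """

    mode: str = "FB"
    resp_amplitude: tuple[float, float, float] = (2.0, 8.0, 3.0)
    resp_period: float = 4.0
    cardiac_amplitude: tuple[float, float, float] = (1.0, 1.5, 1.0)
    cardiac_rate: float = 70.0
    baseline: tuple[float, float, float] = (0.0, 0.0, 0.0)
    drift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    resp_phase: float = 0.0
    cardiac_phase: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if min(self.resp_amplitude) < 0 or min(self.cardiac_amplitude) < 0:
            raise ValueError("motion amplitudes must be >= 0")
        if self.resp_period <= 0 or self.cardiac_rate < 0:
            raise ValueError("resp_period must be > 0 and cardiac_rate >= 0")

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "MotionModel":
        """Default motion parameters per motion-management regime.

        DIBH keeps a small residual respiratory drift (breath-holds are
        never perfectly static); AC damps the free-breathing amplitude;
        HFV trades amplitude for frequency.
        """
        defaults = {
            "DIBH": dict(resp_amplitude=(0.3, 1.0, 0.5), resp_period=12.0),
            "FB": dict(resp_amplitude=(2.0, 8.0, 3.0), resp_period=4.0),
            "AC": dict(resp_amplitude=(1.0, 4.0, 1.5), resp_period=4.0),
            "HFV": dict(resp_amplitude=(0.5, 1.5, 0.8), resp_period=0.24),
        }
        if mode not in defaults:
            raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
        kwargs = dict(defaults[mode], mode=mode)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass(frozen=True)
class LeadTipModel:
    """Cylinder model of the tracked ICD lead tip.

    ``planning_position`` is the 3D tip-center coordinate from the
    planning CT, relative to isocenter; ``axis`` the lead direction at
    planning; ``contrast`` scales the chord length (mm) into image
    intensity units.
    """

    radius: float = 1.0
    length: float = 8.0
    axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    contrast: float = 1.0
    planning_position: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0 or self.contrast <= 0:
            raise ValueError("radius, length and contrast must be > 0")
        n = float(np.linalg.norm(self.axis))
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError(f"axis must be a unit vector (norm {n:.4f})")


@dataclass
class Trajectory3D:
    """Simulated ground-truth trajectory, one entry per projection."""

    positions: np.ndarray  # (n, 3) mm, columns lr/si/ap
    times: np.ndarray  # (n,) s

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        if self.positions.shape != (len(self.times), 3):
            raise ValueError("positions must be (n, 3) matching times length n")

    def __len__(self) -> int:
        return len(self.times)


def _resp_wave(mode: str, t: np.ndarray, period: float, phase: float) -> np.ndarray:
    if mode in ("FB", "AC"):
        # cos^4 gives a flat end-exhale dwell; range [0, 1] with period `period`.
        return np.cos(np.pi * t / period + phase) ** 4
    # DIBH (slow residual) and HFV (fast shallow): plain sinusoid.
    return np.sin(2 * np.pi * t / period + phase)


def simulate_trajectory(model: MotionModel, metas: list[ProjectionMeta]) -> Trajectory3D:
    """Evaluate the motion model at each projection time."""
    if not metas:
        raise ValueError("metas must be non-empty")
    t = np.array([m.time for m in metas], dtype=float)
    resp = np.asarray(model.resp_amplitude)[None, :] * _resp_wave(
        model.mode, t, model.resp_period, model.resp_phase
    )[:, None]
    cardiac = np.asarray(model.cardiac_amplitude)[None, :] * np.sin(
        2 * np.pi * model.cardiac_rate / 60.0 * t + model.cardiac_phase
    )[:, None]
    pos = (
        np.asarray(model.baseline)[None, :]
        + np.asarray(model.drift)[None, :] * t[:, None]
        + resp
        + cardiac
    )
    return Trajectory3D(positions=pos, times=t)


def cylinder_chords(
    u: np.ndarray,
    v: np.ndarray,
    center_beam: np.ndarray,
    axis_beam: np.ndarray,
    radius: float,
    half_length: float,
) -> np.ndarray:
    """Chord lengths of parallel rays through a finite cylinder.

    ``u, v`` are the resolved ray coordinates at isocenter scale (mm);
    rays run along the beam depth axis. ``center_beam``/``axis_beam`` are
    the cylinder center and unit axis expressed in the beam frame
    (u, v, w). Returns chord length in mm per ray, vectorized.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    d = np.array([0.0, 0.0, 1.0])
    ah = np.asarray(axis_beam, dtype=float)
    # delta = ray anchor (u, v, 0) minus cylinder center
    du = u - center_beam[0]
    dv = v - center_beam[1]
    dw = -center_beam[2]
    az = float(d @ ah)
    m0 = du * ah[0] + dv * ah[1] + dw * ah[2]

    # radial quadratic |delta_perp + s d_perp|^2 = r^2
    dpu, dpv, dpw = -ah[0] * az, -ah[1] * az, 1.0 - az * az
    epu = du - m0 * ah[0]
    epv = dv - m0 * ah[1]
    epw = dw - m0 * ah[2]
    A = dpu * dpu + dpv * dpv + dpw * dpw
    B = epu * dpu + epv * dpv + epw * dpw
    C = epu * epu + epv * epv + epw * epw - radius * radius

    big = 1e9
    if A > 1e-12:
        disc = B * B - A * C
        hit = disc > 0
        sq = np.sqrt(np.where(hit, disc, 0.0))
        r_lo = np.where(hit, (-B - sq) / A, big)
        r_hi = np.where(hit, (-B + sq) / A, -big)
    else:  # ray parallel to the cylinder axis
        inside = C <= 0
        r_lo = np.where(inside, -big, big)
        r_hi = np.where(inside, big, -big)

    # axial slab |m0 + s*az| <= half_length
    if abs(az) > 1e-12:
        s1 = (-half_length - m0) / az
        s2 = (half_length - m0) / az
        a_lo = np.minimum(s1, s2)
        a_hi = np.maximum(s1, s2)
    else:
        inside = np.abs(m0) <= half_length
        a_lo = np.where(inside, -big, big)
        a_hi = np.where(inside, big, -big)

    return np.maximum(0.0, np.minimum(r_hi, a_hi) - np.maximum(r_lo, a_lo))


def render_cylinder_window(
    tip_position,
    tip_axis,
    gantry_angle: float,
    geom: BeamGeometry,
    radius: float,
    length: float,
    contrast: float,
    margin_px: int = 6,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Render the cylinder footprint into a minimal pixel window.

    Returns ``(window, (col0, row0))`` where ``window`` holds
    ``contrast * chord_length`` per pixel and ``(col0, row0)`` is the
    window origin in imager pixel coordinates. The window is clipped to
    the imager; pixels are sampled at their centers with one ray each
    (parallel-beam at nominal magnification).
    """
    p = np.asarray(tip_position, dtype=float)
    a, b, c = beam_frame(gantry_angle)
    u_mm, v_mm = project_point(p, gantry_angle, geom)
    col_c, row_c = imager_mm_to_px(u_mm, v_mm, geom)

    half_extent_mm = (length / 2.0 + radius) * geom.magnification
    half_px = int(np.ceil(half_extent_mm / geom.pixel_spacing)) + margin_px
    cols, rows = geom.imager_size
    col0 = max(0, int(round(col_c)) - half_px)
    col1 = min(cols, int(round(col_c)) + half_px + 1)
    row0 = max(0, int(round(row_c)) - half_px)
    row1 = min(rows, int(round(row_c)) + half_px + 1)
    if col0 >= col1 or row0 >= row1:
        raise ValueError(
            f"tip projects outside the imager at gantry angle {gantry_angle:.1f} deg"
        )

    cc, rr = np.meshgrid(np.arange(col0, col1), np.arange(row0, row1))
    cx, cy = geom.imager_center
    # Pixel centers -> imager mm -> resolved coordinates at the *object*
    # depth. Using the local magnification sdd/(sad - w0) anchors the
    # parallel-ray bundle on the true divergent projection of the tip.
    w0 = float(c @ p)
    local_mag = geom.sdd / (geom.sad - w0)
    u_iso = (cc - cx) * geom.pixel_spacing / local_mag
    v_iso = (cy - rr) * geom.pixel_spacing / local_mag

    axis = np.asarray(tip_axis, dtype=float)
    center_beam = np.array([a @ p, b @ p, w0])
    axis_beam = np.array([a @ axis, b @ axis, c @ axis])
    chords = cylinder_chords(u_iso, v_iso, center_beam, axis_beam, radius, length / 2.0)
    return contrast * chords, (col0, row0)


@dataclass(frozen=True)
class ClutterSpec:
    """Straight high-contrast wire segments overlaid on projections.

    Each wire is a line through ``offset_px`` (relative to the projected
    tip position) at ``angle_deg`` in image coordinates, ``width_px``
    wide, with the given intensity.
    """

    offsets_px: tuple[tuple[float, float], ...] = ((-15.0, 10.0),)
    angles_deg: tuple[float, ...] = (30.0,)
    width_px: float = 2.0
    intensity: float = 2.0


def _render_clutter(
    image: np.ndarray, anchor_colrow: tuple[float, float], clutter: ClutterSpec
) -> None:
    rows, cols = image.shape
    cc, rr = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    for (dc, dr), ang in zip(clutter.offsets_px, clutter.angles_deg):
        c0 = anchor_colrow[0] + dc
        r0 = anchor_colrow[1] + dr
        th = np.deg2rad(ang)
        # perpendicular distance to the infinite line through (c0, r0)
        dist = np.abs(-(cc - c0) * np.sin(th) + (rr - r0) * np.cos(th))
        image[dist <= clutter.width_px / 2.0] += clutter.intensity


def render_projection(
    tip_position,
    tip_axis,
    gantry_angle: float,
    geom: BeamGeometry,
    lead: LeadTipModel | None = None,
    noise_sd: float = 0.0,
    clutter: ClutterSpec | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one kV projection (rows x cols, float) of the moving tip.

    Background is 0; the cylinder contributes ``contrast * chord`` per
    pixel; optional wire clutter is added before white Gaussian noise
    with standard deviation ``noise_sd``.
    """
    lead = lead or LeadTipModel()
    cols, rows = geom.imager_size
    image = np.zeros((rows, cols), dtype=float)
    window, (col0, row0) = render_cylinder_window(
        tip_position, tip_axis, gantry_angle, geom, lead.radius, lead.length, lead.contrast
    )
    image[row0 : row0 + window.shape[0], col0 : col0 + window.shape[1]] += window
    if clutter is not None:
        u_mm, v_mm = project_point(np.asarray(tip_position, float), gantry_angle, geom)
        anchor = imager_mm_to_px(u_mm, v_mm, geom)
        _render_clutter(image, (float(anchor[0]), float(anchor[1])), clutter)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        image += rng.normal(0.0, noise_sd, size=image.shape)
    return image


def default_metas(
    n_projections: int = 368, arc_deg: float = 360.0, duration_s: float = 60.0
) -> list[ProjectionMeta]:
    """Uniform gantry sweep: angles over [0, arc) and times over [0, duration)."""
    if n_projections < 1:
        raise ValueError("n_projections must be >= 1")
    return [
        ProjectionMeta(
            index=i,
            gantry_angle=i * arc_deg / n_projections,
            time=i * duration_s / n_projections,
        )
        for i in range(n_projections)
    ]


def write_stack(path, frames: np.ndarray) -> None:
    """Write a float projection stack as multi-frame 16-bit TIFF.

    Intensities are quantized with a global scale factor recorded in the
    TIFF ImageDescription so :func:`read_stack` restores float values.
    """
    frames = np.asarray(frames, dtype=float)
    lo = float(frames.min())
    hi = float(frames.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    quant = np.round((frames - lo) / scale).astype(np.uint16)
    desc = json.dumps({"offset": lo, "scale": scale})
    tifffile.imwrite(path, quant, description=desc, photometric="minisblack")


def read_stack(path) -> np.ndarray:
    """Read a projection stack written by :func:`write_stack`.

    Plain (unscaled) TIFF stacks load as raw float values.
    """
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray().astype(float)
        if frames.ndim == 2:
            frames = frames[None, :, :]
        desc = tif.pages[0].description
    if desc:
        try:
            meta = json.loads(desc)
            frames = frames * float(meta["scale"]) + float(meta["offset"])
        except (ValueError, KeyError, TypeError):
            pass
    return frames


@dataclass(frozen=True)
class DatasetConfig:
    """Everything needed to generate one synthetic CBCT scan."""

    motion: MotionModel = field(default_factory=MotionModel)
    lead: LeadTipModel = field(default_factory=LeadTipModel)
    geom: BeamGeometry = field(default_factory=BeamGeometry)
    n_projections: int = 368
    arc_deg: float = 360.0
    duration_s: float = 60.0
    noise_sd: float = 0.1
    clutter: ClutterSpec | None = None


def generate_dataset(
    config: DatasetConfig, seed: int, outdir, overwrite: bool = False
) -> dict[str, Path]:
    """Generate and write a complete self-consistent synthetic scan.

    Writes ``projections.tiff``, ``geometry.json``, ``planning_tip.json``
    and ``ground_truth.csv`` (columns
    ``index,time_s,gantry_deg,lr_mm,si_mm,ap_mm,u_px,v_px``) under
    ``outdir``. Deterministic for a given seed and config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "projections": outdir / "projections.tiff",
        "geometry": outdir / "geometry.json",
        "planning_tip": outdir / "planning_tip.json",
        "ground_truth": outdir / "ground_truth.csv",
    }
    existing = [str(p) for p in paths.values() if p.exists()]
    if existing and not overwrite:
        raise FileExistsError(
            f"refusing to overwrite existing output(s) {existing}; pass overwrite=True"
        )

    rng = np.random.default_rng(seed)
    metas = default_metas(config.n_projections, config.arc_deg, config.duration_s)
    motion = replace(config.motion, rng_seed=seed)
    traj = simulate_trajectory(motion, metas)

    geom = config.geom
    frames = np.empty(
        (len(metas), geom.imager_size[1], geom.imager_size[0]), dtype=float
    )
    truth_rows = []
    for m, pos in zip(metas, traj.positions):
        frames[m.index] = render_projection(
            pos,
            config.lead.axis,
            m.gantry_angle,
            geom,
            lead=config.lead,
            noise_sd=config.noise_sd,
            clutter=config.clutter,
            rng=rng,
        )
        u_mm, v_mm = project_point(pos, m.gantry_angle, geom)
        col, row = imager_mm_to_px(u_mm, v_mm, geom)
        truth_rows.append(
            (m.index, m.time, m.gantry_angle, pos[0], pos[1], pos[2], float(col), float(row))
        )

    write_stack(paths["projections"], frames)
    save_geometry(paths["geometry"], geom, metas)
    paths["planning_tip"].write_text(
        json.dumps(
            {
                "position_mm": list(config.lead.planning_position),
                "axis": list(config.lead.axis),
                "radius_mm": config.lead.radius,
                "length_mm": config.lead.length,
            },
            indent=1,
        )
    )
    header = "index,time_s,gantry_deg,lr_mm,si_mm,ap_mm,u_px,v_px"
    lines = [header] + [
        f"{i},{t:.6f},{g:.6f},{lr:.6f},{si:.6f},{ap:.6f},{u:.6f},{v:.6f}"
        for i, t, g, lr, si, ap, u, v in truth_rows
    ]
    paths["ground_truth"].write_text("\n".join(lines) + "\n")
    return paths
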