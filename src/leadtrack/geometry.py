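"""Cone-beam acquisition geometry and 2D/3D coordinate transforms.

Room coordinates are patient axes relative to the machine isocenter,
ordered ``(lr, si, ap)`` in mm: LR positive toward patient left, SI
positive superior, AP positive anterior. The kV source and flat-panel
imager rotate rigidly about the SI axis; at gantry angle 0 deg the source
sits anterior to the patient and the beam travels anterior-to-posterior.

For a projection at gantry angle ``theta`` the *resolved* coordinates are
the two room-frame components measurable on the imager (the in-plane
lateral direction and SI); the *unresolved* coordinate is the depth along
the ray toward the source, which a single projection cannot measure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "BeamGeometry",
    "ProjectionMeta",
    "beam_frame",
    "project_point",
    "backproject_resolved",
    "imager_mm_to_px",
    "imager_px_to_mm",
    "load_geometry",
    "save_geometry",
]


@dataclass(frozen=True)
class BeamGeometry:
    """CBCT acquisition constants shared by every projection of a scan.

    Parameters
    ----------
    sad : float
        Source-to-isocenter distance in mm.
    sdd : float
        Source-to-imager distance in mm.
    pixel_spacing : float
        Imager pixel size in mm/pixel, identical in both imager axes.
        The default of 0.8 mm/px makes 25 pixels correspond to 20 mm.
    imager_size : tuple[int, int]
        Panel size as (columns, rows) in pixels.
    """

    sad: float = 1000.0
    sdd: float = 1500.0
    pixel_spacing: float = 0.8
    imager_size: tuple[int, int] = (512, 384)

    def __post_init__(self) -> None:
        if not (self.sdd > self.sad > 0):
            raise ValueError(
                f"require sdd > sad > 0, got sad={self.sad}, sdd={self.sdd}"
            )
        if self.pixel_spacing <= 0:
            raise ValueError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")
        cols, rows = self.imager_size
        if cols < 1 or rows < 1:
            raise ValueError(f"imager_size components must be >= 1, got {self.imager_size}")

    @property
    def magnification(self) -> float:
        """Nominal magnification ``M0 = sdd / sad`` at isocenter depth."""
        return self.sdd / self.sad

    @property
    def imager_center(self) -> tuple[float, float]:
        """(col, row) pixel coordinate of the imager center / beam axis."""
        cols, rows = self.imager_size
        return (cols - 1) / 2.0, (rows - 1) / 2.0


@dataclass(frozen=True)
class ProjectionMeta:
    """Per-projection acquisition metadata."""

    index: int
    gantry_angle: float
    time: float

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"projection index must be >= 0, got {self.index}")


def beam_frame(gantry_angle: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal beam frame ``(a, b, c)`` at a gantry angle in degrees.

    ``a`` is the resolved lateral direction on the imager, ``b`` the
    resolved vertical direction (always SI), and ``c`` the unresolved
    depth direction pointing from isocenter toward the source. All three
    are unit vectors over room axes ``(lr, si, ap)`` and the triple is
    right-handed.
    """
    th = np.deg2rad(gantry_angle)
    a = np.array([np.cos(th), 0.0, np.sin(th)])
    b = np.array([0.0, 1.0, 0.0])
    c = np.array([-np.sin(th), 0.0, np.cos(th)])
    return a, b, c


def project_point(p, gantry_angle: float, geom: BeamGeometry) -> tuple[float, float]:
    """Forward-project a room point onto the imager plane.

    Returns ``(u, v)`` in mm from the imager center: ``u`` along the
    resolved lateral axis, ``v`` along SI. Divergent (cone-beam)
    magnification ``sdd / (sad - w)`` is applied, where ``w`` is the depth
    of the point toward the source.

    Raises
    ------
    ValueError
        If the point lies at or behind the source (``w >= sad``).
    """
    p = np.asarray(p, dtype=float)
    a, b, c = beam_frame(gantry_angle)
    w = float(c @ p)
    if w >= geom.sad:
        raise ValueError(
            f"point depth w={w:.1f} mm is at/behind the source (sad={geom.sad} mm)"
        )
    mag = geom.sdd / (geom.sad - w)
    return float(a @ p) * mag, float(b @ p) * mag


def backproject_resolved(
    u: float,
    v: float,
    gantry_angle: float,
    geom: BeamGeometry,
    depth_guess: float = 0.0,
) -> tuple[float, float]:
    """Scale imager-plane mm coordinates back to isocenter scale.

    With ``depth_guess = 0`` this is the fixed nominal-magnification
    approximation; passing the true depth of the point inverts
    :func:`project_point` exactly. The gantry angle is accepted for
    interface symmetry with :func:`project_point` (the scaling itself is
    angle-independent).
    """
    del gantry_angle  # scaling is the same at every angle
    if depth_guess >= geom.sad:
        raise ValueError(
            f"depth_guess={depth_guess} mm is at/behind the source (sad={geom.sad} mm)"
        )
    scale = (geom.sad - depth_guess) / geom.sdd
    return u * scale, v * scale


def imager_mm_to_px(u, v, geom: BeamGeometry):
    """Convert imager-plane mm offsets from center to (col, row) pixels.

    Rows increase inferior (down the image), so ``+v`` (superior) maps to
    smaller row indices.
    """
    cx, cy = geom.imager_center
    return np.asarray(u) / geom.pixel_spacing + cx, cy - np.asarray(v) / geom.pixel_spacing


def imager_px_to_mm(col, row, geom: BeamGeometry):
    """Inverse of :func:`imager_mm_to_px`."""
    cx, cy = geom.imager_center
    return (np.asarray(col) - cx) * geom.pixel_spacing, (cy - np.asarray(row)) * geom.pixel_spacing


_GEOMETRY_KEYS = ("sad_mm", "sdd_mm", "pixel_spacing_mm", "imager_size_px", "angles_deg")


def load_geometry(path) -> tuple[BeamGeometry, list[ProjectionMeta]]:
    """Read an acquisition-geometry descriptor (JSON).

    Required keys: ``sad_mm, sdd_mm, pixel_spacing_mm, imager_size_px,
    angles_deg``; ``times_s`` is optional (defaults to projection index in
    seconds / uniform spacing is *not* assumed).
    """
    with open(path) as fh:
        data = json.load(fh)
    missing = [k for k in _GEOMETRY_KEYS if k not in data]
    if missing:
        raise KeyError(
            f"geometry descriptor {path} is missing required key(s): {', '.join(missing)}"
        )
    geom = BeamGeometry(
        sad=float(data["sad_mm"]),
        sdd=float(data["sdd_mm"]),
        pixel_spacing=float(data["pixel_spacing_mm"]),
        imager_size=tuple(int(x) for x in data["imager_size_px"]),
    )
    angles = [float(x) for x in data["angles_deg"]]
    times = data.get("times_s")
    if times is None:
        times = list(range(len(angles)))
    if len(times) != len(angles):
        raise ValueError(
            f"times_s has {len(times)} entries but angles_deg has {len(angles)}"
        )
    metas = [
        ProjectionMeta(index=i, gantry_angle=ang, time=float(t))
        for i, (ang, t) in enumerate(zip(angles, times))
    ]
    return geom, metas


def save_geometry(path, geom: BeamGeometry, metas: list[ProjectionMeta]) -> None:
    """Write the geometry descriptor consumed by :func:`load_geometry`."""
    data = {
        "sad_mm": geom.sad,
        "sdd_mm": geom.sdd,
        "pixel_spacing_mm": geom.pixel_spacing,
        "imager_size_px": list(geom.imager_size),
        "angles_deg": [m.gantry_angle for m in metas],
        "times_s": [m.time for m in metas],
    }
    Path(path).write_text(json.dumps(data, indent=1))
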