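"""Per-projection 2D lead-tip localization by template matching.

For every kV projection the planning-CT tip coordinate is forward
projected onto the imager and a 70 x 70 pixel search region extracted
around it. A bank of cylinder templates — the lead rendered as seen at
that gantry angle, rotated in-plane at 5 degree intervals (8 rotations
for breath-hold scans, 20 for free-breathing / abdominal-compression /
high-frequency-ventilation scans, whose cardiorespiratory motion tilts
the lead further) and at three sizes — is slid across the region with
normalized cross-correlation. The placement, rotation and size with the
highest NCC score give the segmented position, reported as the
intensity-weighted centroid of the winning template footprint.

Matching is integer-pixel; no subpixel refinement is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.feature import match_template

from .geometry import BeamGeometry, ProjectionMeta, beam_frame, imager_mm_to_px, project_point
from .phantom import LeadTipModel, render_cylinder_window

__all__ = [
    "SEARCH_REGION_SIZE",
    "SearchRegion",
    "TemplateBank",
    "Segmentation2D",
    "expected_2d_position",
    "extract_search_region",
    "build_template_bank",
    "ncc_map",
    "match",
    "segment_scan",
]

SEARCH_REGION_SIZE = 70
ROTATION_STEP_DEG = 5.0
N_ROTATIONS = {"DIBH": 8, "FB": 20, "AC": 20, "HFV": 20}
SCALES = (0.9, 1.0, 1.1)


@dataclass(frozen=True)
class SearchRegion:
    """A 70 x 70 crop of one projection plus its imager-pixel origin."""

    pixels: np.ndarray  # (70, 70) float
    origin: tuple[int, int]  # (col, row) of the crop's top-left corner
    projection_index: int

    def __post_init__(self) -> None:
        if self.pixels.shape != (SEARCH_REGION_SIZE, SEARCH_REGION_SIZE):
            raise ValueError(
                f"search region must be {SEARCH_REGION_SIZE}x{SEARCH_REGION_SIZE}, "
                f"got {self.pixels.shape}"
            )


@dataclass(frozen=True)
class TemplateEntry:
    image: np.ndarray
    rotation_offset: float  # degrees, in-plane, relative to planning orientation
    scale: float


@dataclass(frozen=True)
class TemplateBank:
    """Cylinder templates indexed by (rotation offset, scale)."""

    entries: tuple[TemplateEntry, ...]
    gantry_angle: float

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class Segmentation2D:
    """Best NCC match for one projection.

    ``centroid`` is the intensity-weighted centroid of the winning
    template footprint in imager (col, row) pixel coordinates — the
    centroid of the segmented area, not the placement corner.
    """

    projection_index: int
    centroid: tuple[float, float]  # (col, row) px
    ncc_score: float
    rotation_offset: float
    scale: float
    accepted: bool = True


def expected_2d_position(
    planning_tip, gantry_angle: float, geom: BeamGeometry
) -> tuple[float, float]:
    """Forward-project the planning tip to imager (col, row) pixels."""
    u_mm, v_mm = project_point(np.asarray(planning_tip, float), gantry_angle, geom)
    col, row = imager_mm_to_px(u_mm, v_mm, geom)
    cols, rows = geom.imager_size
    if not (0 <= col < cols and 0 <= row < rows):
        raise ValueError(
            f"planning tip projects outside the imager at ({col:.1f}, {row:.1f}) px"
        )
    return float(col), float(row)


def extract_search_region(
    image: np.ndarray, center: tuple[float, float], projection_index: int = 0
) -> SearchRegion:
    """Crop the 70 x 70 search region centered at ``center`` (col, row).

    Crops that would overrun the image boundary are shifted to stay fully
    inside (no padding), with the shift recorded in ``origin`` so that
    region-local coordinates map back to the imager exactly.
    """
    rows, cols = image.shape
    size = SEARCH_REGION_SIZE
    if rows < size or cols < size:
        raise ValueError(f"image {image.shape} is smaller than {size}x{size}")
    col0 = int(round(center[0])) - size // 2
    row0 = int(round(center[1])) - size // 2
    col0 = min(max(col0, 0), cols - size)
    row0 = min(max(row0, 0), rows - size)
    crop = image[row0 : row0 + size, col0 : col0 + size]
    return SearchRegion(pixels=crop, origin=(col0, row0), projection_index=projection_index)


def _rotate_in_plane(axis_beam: np.ndarray, offset_deg: float) -> np.ndarray:
    """Rotate the in-plane (u, v) component of a beam-frame axis."""
    g = np.deg2rad(offset_deg)
    p, q, w = axis_beam
    return np.array(
        [p * np.cos(g) - q * np.sin(g), p * np.sin(g) + q * np.cos(g), w]
    )


def _render_template(
    lead: LeadTipModel,
    gantry_angle: float,
    geom: BeamGeometry,
    rotation_offset: float,
    scale: float,
    margin_px: int = 2,
) -> np.ndarray:
    """Noiseless cylinder projection, tight bounding box + 2 px margin.

    The template is rendered with the same chord-length projector as the
    phantom, with the lead axis rotated in-plane by ``rotation_offset``
    about the beam axis and the cylinder isotropically scaled.
    """
    a, b, c = beam_frame(gantry_angle)
    axis = np.asarray(lead.axis, dtype=float)
    axis_beam = np.array([a @ axis, b @ axis, c @ axis])
    axis_rot_beam = _rotate_in_plane(axis_beam, rotation_offset)
    axis_room = axis_rot_beam[0] * a + axis_rot_beam[1] * b + axis_rot_beam[2] * c
    # render at isocenter (depth 0) so the template sees nominal magnification
    window, _ = render_cylinder_window(
        np.zeros(3),
        axis_room,
        gantry_angle,
        geom,
        radius=lead.radius * scale,
        length=lead.length * scale,
        contrast=lead.contrast,
        margin_px=margin_px + 2,
    )
    nz_rows = np.flatnonzero(window.any(axis=1))
    nz_cols = np.flatnonzero(window.any(axis=0))
    if nz_rows.size == 0:
        raise ValueError("degenerate cylinder produced an empty template")
    r0 = max(0, nz_rows[0] - margin_px)
    r1 = min(window.shape[0], nz_rows[-1] + 1 + margin_px)
    c0 = max(0, nz_cols[0] - margin_px)
    c1 = min(window.shape[1], nz_cols[-1] + 1 + margin_px)
    template = window[r0:r1, c0:c1]
    if template.std() == 0:
        raise ValueError("degenerate cylinder: template has zero intensity variance")
    return template


def build_template_bank(
    lead: LeadTipModel,
    gantry_angle: float,
    geom: BeamGeometry,
    mode: str,
    scales: tuple[float, ...] = SCALES,
) -> TemplateBank:
    """Template bank at one gantry angle: n rotations x len(scales) sizes.

    Rotation offsets are consecutive multiples of 5 degrees centered on
    the planning orientation, ``(k - (n-1)/2) * 5`` for k = 0..n-1, with
    n = 8 for DIBH and 20 for FB/AC/HFV.
    """
    try:
        n = N_ROTATIONS[mode]
    except KeyError:
        raise ValueError(f"mode must be one of {sorted(N_ROTATIONS)}, got {mode!r}")
    offsets = [(k - (n - 1) / 2.0) * ROTATION_STEP_DEG for k in range(n)]
    entries = [
        TemplateEntry(
            image=_render_template(lead, gantry_angle, geom, off, s),
            rotation_offset=off,
            scale=s,
        )
        for off in offsets
        for s in scales
    ]
    return TemplateBank(entries=tuple(entries), gantry_angle=gantry_angle)


def ncc_map(region: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of a template slid across a region.

    Each valid placement scores the Pearson correlation between the
    template and the covered patch (both mean-subtracted and normalized
    over the template footprint). Output shape is
    ``(R - r + 1, C - c + 1)``; placements where the patch has zero
    variance score 0.
    """
    region = np.asarray(region, dtype=float)
    template = np.asarray(template, dtype=float)
    if template.shape[0] >= region.shape[0] or template.shape[1] >= region.shape[1]:
        raise ValueError(
            f"template {template.shape} must be strictly smaller than region {region.shape}"
        )
    if template.std() == 0:
        raise ValueError("template has zero intensity variance")
    out = match_template(region, template, pad_input=False)
    out = np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)
    return np.clip(out, -1.0, 1.0)


def _template_centroid(template: np.ndarray) -> tuple[float, float]:
    """Intensity-weighted centroid (col, row) of the above-zero footprint."""
    mask = template > 0
    w = np.where(mask, template, 0.0)
    total = w.sum()
    rr, cc = np.mgrid[0 : template.shape[0], 0 : template.shape[1]]
    return float((w * cc).sum() / total), float((w * rr).sum() / total)


def match(region: SearchRegion, bank: TemplateBank) -> Segmentation2D:
    """Best match over all placements, rotations and scales.

    The global NCC argmax wins; exact ties break toward the smallest
    absolute rotation offset (negative before positive), then the scale
    closest to 1.0 (smaller first), then the smallest row-major placement
    index.
    """
    if not bank.entries:
        raise ValueError("template bank is empty")
    order = sorted(
        range(len(bank.entries)),
        key=lambda i: (
            abs(bank.entries[i].rotation_offset),
            bank.entries[i].rotation_offset,
            abs(bank.entries[i].scale - 1.0),
            bank.entries[i].scale,
        ),
    )
    best_score = -np.inf
    best_entry = None
    best_pos = (0, 0)
    for i in order:
        entry = bank.entries[i]
        score_map = ncc_map(region.pixels, entry.image)
        flat = int(np.argmax(score_map))
        score = float(score_map.flat[flat])
        if score > best_score:  # strict: earlier (tie-preferred) entries win ties
            best_score = score
            best_entry = entry
            best_pos = np.unravel_index(flat, score_map.shape)
    tc, tr = _template_centroid(best_entry.image)
    col = region.origin[0] + best_pos[1] + tc
    row = region.origin[1] + best_pos[0] + tr
    return Segmentation2D(
        projection_index=region.projection_index,
        centroid=(col, row),
        ncc_score=best_score,
        rotation_offset=best_entry.rotation_offset,
        scale=best_entry.scale,
    )


def segment_scan(
    stack: np.ndarray,
    geom: BeamGeometry,
    metas: list[ProjectionMeta],
    lead: LeadTipModel,
    mode: str,
    min_ncc: float | None = None,
    log=None,
) -> list[Segmentation2D]:
    """Segment every projection of a scan, in order.

    ``min_ncc`` optionally pre-flags low-score matches (tip likely not
    visible) as not accepted; by default every frame emits a match with
    its score and acceptance is left to the downstream filter.
    """
    if len(stack) != len(metas):
        raise ValueError(
            f"stack has {len(stack)} frames but metadata lists {len(metas)} projections"
        )
    segs = []
    for meta, frame in zip(metas, stack):
        try:
            center = expected_2d_position(lead.planning_position, meta.gantry_angle, geom)
            region = extract_search_region(frame, center, projection_index=meta.index)
            bank = build_template_bank(lead, meta.gantry_angle, geom, mode)
            seg = match(region, bank)
        except ValueError as exc:
            raise ValueError(f"projection {meta.index}: {exc}") from exc
        if min_ncc is not None and seg.ncc_score < min_ncc:
            seg = replace(seg, accepted=False)
        if log is not None:
            log.debug(
                "frame %d: ncc=%.3f rot=%+.1f scale=%.1f at (%.1f, %.1f)",
                meta.index, seg.ncc_score, seg.rotation_offset, seg.scale,
                seg.centroid[0], seg.centroid[1],
            )
        segs.append(seg)
    return segs
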