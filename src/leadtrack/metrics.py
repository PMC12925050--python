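"""Evaluation metrics: segmentation success, motion displacement,
3D estimation error and the filtered-vs-raw statistical comparison.

Conventions follow the tracking study design: a 2D segmentation is
successful when its error is below 2 mm (CT slice thickness) in *both*
imager axes separately; motion displacement is the absolute deviation of
each position from the scan-mean position, summarized by the 5th-95th
percentile range; 3D estimation succeeds when the error is below 2 mm on
all three axes simultaneously. Percentiles use linear interpolation
between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .estimation import TrajectoryEstimate

__all__ = [
    "DisplacementSummary",
    "AccuracyReport",
    "segmentation_success",
    "displacement_summary",
    "estimation_errors",
    "wilcoxon_signed_rank",
]

AXES = ("lr", "si", "ap")


@dataclass(frozen=True)
class DisplacementSummary:
    """Per-axis displacement percentiles (mm): {axis: (p5, median, p95)}."""

    per_axis: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for ax, (p5, med, p95) in self.per_axis.items():
            if not (0 <= p5 <= med <= p95):
                raise ValueError(f"{ax}: require 0 <= p5 <= median <= p95")


@dataclass(frozen=True)
class AccuracyReport:
    """Success fraction and signed per-axis error percentiles (mm)."""

    fraction_success: float
    per_axis_percentiles: dict[str, tuple[float, float, float]]  # (p5, median, p95)
    n_evaluated: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_success <= 1.0):
            raise ValueError("fraction_success must be in [0, 1]")


def _match_indices(idx_a, idx_b) -> tuple[np.ndarray, np.ndarray]:
    common, ia, ib = np.intersect1d(idx_a, idx_b, return_indices=True)
    if common.size == 0:
        raise ValueError("no overlapping projection indices to compare")
    return ia, ib


def segmentation_success(
    segs,
    truth_px: dict[int, tuple[float, float]],
    pixel_spacing: float,
    threshold_mm: float = 2.0,
    accepted_only: bool = False,
) -> AccuracyReport:
    """Fraction of segmentations within ``threshold_mm`` of truth per axis.

    ``truth_px`` maps projection index to ground-truth (col, row). Errors
    are pixel differences scaled to mm; success requires both axis errors
    strictly below the threshold.
    """
    evaluated = [
        s for s in segs if s.projection_index in truth_px and (s.accepted or not accepted_only)
    ]
    if not evaluated:
        raise ValueError("no segmentations overlap the ground truth")
    err = np.array(
        [
            [
                (s.centroid[0] - truth_px[s.projection_index][0]) * pixel_spacing,
                (s.centroid[1] - truth_px[s.projection_index][1]) * pixel_spacing,
            ]
            for s in evaluated
        ]
    )
    success = np.all(np.abs(err) < threshold_mm, axis=1)
    pct = np.percentile(err, [5, 50, 95], axis=0)
    return AccuracyReport(
        fraction_success=float(np.mean(success)),
        per_axis_percentiles={
            "x": tuple(float(v) for v in pct[:, 0]),
            "y": tuple(float(v) for v in pct[:, 1]),
        },
        n_evaluated=len(evaluated),
    )


def displacement_summary(traj: TrajectoryEstimate) -> DisplacementSummary:
    """Motion displacement relative to the scan-mean position.

    The mean position is the average over all time points; displacement
    is the absolute per-axis deviation from it, summarized by the 5th
    and 95th percentiles (and the median).
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 trajectory points")
    dev = np.abs(traj.positions - traj.positions.mean(axis=0))
    pct = np.percentile(dev, [5, 50, 95], axis=0)
    return DisplacementSummary(
        per_axis={
            ax: (float(pct[0, i]), float(pct[1, i]), float(pct[2, i]))
            for i, ax in enumerate(AXES)
        }
    )


def estimation_errors(
    est: TrajectoryEstimate, ref: TrajectoryEstimate, threshold_mm: float = 2.0
) -> AccuracyReport:
    """Signed per-axis 3D errors of ``est`` against a reference trajectory.

    A frame succeeds when the absolute error is strictly below the
    threshold on all three axes; only frames present in both trajectories
    are evaluated.
    """
    ia, ib = _match_indices(est.indices, ref.indices)
    err = est.positions[ia] - ref.positions[ib]
    success = np.all(np.abs(err) < threshold_mm, axis=1)
    pct = np.percentile(err, [5, 50, 95], axis=0)
    return AccuracyReport(
        fraction_success=float(np.mean(success)),
        per_axis_percentiles={
            ax: (float(pct[0, i]), float(pct[1, i]), float(pct[2, i]))
            for i, ax in enumerate(AXES)
        },
        n_evaluated=int(len(ia)),
    )


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test with two-sided p value.

    Zero differences are dropped and ties receive midranks. For n <= 12
    retained pairs the p value is exact, by enumeration of all 2^n sign
    assignments of the observed |differences|; for larger n the normal
    approximation with tie correction is used. Returns ``(W+, p)`` where
    W+ is the positive-rank sum.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    absd = np.abs(d)
    # midranks of |d|
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_abs[j] == sorted_abs[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average of ranks i+1..j
        i = j
    w_plus = float(ranks[d > 0].sum())

    if n <= 12:
        # exact: distribution of W+ over all equiprobable sign assignments
        totals = np.array(
            [float(np.dot(signs, ranks)) for signs in product((0.0, 1.0), repeat=n)]
        )
        p_le = np.mean(totals <= w_plus + 1e-12)
        p_ge = np.mean(totals >= w_plus - 1e-12)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(absd, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        from scipy.stats import norm

        z = (w_plus - mean) / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return w_plus, p
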