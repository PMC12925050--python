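"""Online rejection of gross 2D segmentation outliers.

Large template-matching failures (wires, overlapping leads) land far from
the true tip, predominantly along the superior-inferior axis where
respiratory excursion is largest. The filter keeps a running mean of the
accepted SI (row) pixel values, updated iteratively as segmentations
stream in so the scheme stays real-time capable, and rejects any
segmentation deviating from that mean by more than 25 pixels (20 mm at
the default 0.8 mm/px spacing). Only accepted segmentations update the
mean; only the SI coordinate is filtered.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .segmentation import Segmentation2D

__all__ = ["FilterState", "update_and_filter", "filter_scan"]


@dataclass(frozen=True)
class FilterState:
    """Running state of the online SI outlier filter.

    The first ``warmup`` segmentations are accepted unconditionally while
    the mean initializes; the paper-equivalent threshold is 25 px = 20 mm.
    """

    threshold: float = 25.0
    warmup: int = 10
    running_mean_si: float = 0.0
    n_accepted: int = 0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        if self.warmup < 1:
            raise ValueError(f"warmup must be >= 1, got {self.warmup}")


def update_and_filter(
    state: FilterState, seg: Segmentation2D
) -> tuple[bool, FilterState]:
    """Accept or reject one segmentation and update the running mean.

    During warmup every segmentation is accepted. Afterwards a
    segmentation is accepted iff its SI (row) value lies within
    ``threshold`` pixels of the running mean of previously accepted
    values. Rejected segmentations leave the state unchanged.
    """
    si = seg.centroid[1]
    in_warmup = state.n_accepted < state.warmup
    if in_warmup or abs(si - state.running_mean_si) <= state.threshold:
        n = state.n_accepted + 1
        new_mean = state.running_mean_si + (si - state.running_mean_si) / n
        return True, replace(state, running_mean_si=new_mean, n_accepted=n)
    return False, state


def filter_scan(
    segs: list[Segmentation2D],
    threshold: float = 25.0,
    warmup: int = 10,
) -> tuple[list[Segmentation2D], float]:
    """Run the online filter over a scan's segmentations, in order.

    Returns the segmentations with ``accepted`` flags set (originals are
    not mutated) and the rejection rate ``rejected / total``.
    """
    if not segs:
        raise ValueError("segs must be non-empty")
    state = FilterState(threshold=threshold, warmup=warmup)
    out = []
    n_rejected = 0
    for seg in segs:
        ok, state = update_and_filter(state, seg)
        if not ok:
            n_rejected += 1
        out.append(replace(seg, accepted=ok))
    return out, n_rejected / len(segs)
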