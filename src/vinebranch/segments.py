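"""Simplified branch models: rectangles, axes, forks, de-duplication.

Each detected "segmented branch" instance is reduced to the minimum
bounding rectangle of its mask and then to the model B = (V, W): the
ordered long-median-axis points V (3 points for an initial segment,
growing as segments are merged into a chain) and the boundary corners W
of the terminal members, which define the sector search rays.  A
"forked branch" instance is reduced to its rectangle's center point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .geometry import OrientedRect, axis_points, min_area_rect, rect_iou
from .masks_io import FORKED, SEGMENTED, InstanceSet

log = logging.getLogger(__name__)

# segment labels are drawn with long/short aspect 2-4; anything flatter
# than this is suspicious for a leaf/petiole false positive
LOW_ASPECT = 1.2


@dataclass(frozen=True)
class Fork:
    """A bifurcation instance, represented by its rectangle center."""

    id: int
    rect: OrientedRect

    @property
    def center(self) -> np.ndarray:
        return self.rect.center


@dataclass(frozen=True)
class BranchSegmentModel:
    """The branch model B = (V, W); also a growing chain of segments.

    ``V`` is the (n, 2) array of axis points ordered top → end; ``W_top``
    holds (w1, w2) of the top-most member rectangle and ``W_end`` holds
    (w3, w4) of the end-most one.  ``member_ids``/``member_rects`` list
    the merged source instances in top → end order.  A side connected to
    a fork is closed for further searching.
    """

    id: int
    V: np.ndarray  # (n, 2)
    W_top: np.ndarray  # (2, 2): w1, w2
    W_end: np.ndarray  # (2, 2): w3, w4
    member_ids: tuple[int, ...]
    member_rects: tuple[OrientedRect, ...]
    top_fork: Optional[Fork] = None
    end_fork: Optional[Fork] = None
    interior_forks: tuple[Fork, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "V", np.asarray(self.V, dtype=float).reshape(-1, 2))
        object.__setattr__(self, "W_top", np.asarray(self.W_top, dtype=float).reshape(2, 2))
        object.__setattr__(self, "W_end", np.asarray(self.W_end, dtype=float).reshape(2, 2))
        if self.V.shape[0] < 3:
            raise ValueError("BranchSegmentModel needs at least 3 axis points")

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    @property
    def forks(self) -> tuple[Fork, ...]:
        out = list(self.interior_forks)
        if self.top_fork is not None:
            out.insert(0, self.top_fork)
        if self.end_fork is not None:
            out.append(self.end_fork)
        return tuple(out)

    def side_closed(self, side: str) -> bool:
        return (self.top_fork if side == "top" else self.end_fork) is not None

    def with_fork(self, side: str, fork: Fork) -> "BranchSegmentModel":
        if self.side_closed(side):
            raise ValueError(f"side {side!r} of model {self.id} is already closed")
        if side == "top":
            return replace(self, top_fork=fork)
        return replace(self, end_fork=fork)


def model_from_rect(instance_id: int, rect: OrientedRect) -> BranchSegmentModel:
    v1, v2, v3 = axis_points(rect)
    return BranchSegmentModel(
        id=instance_id,
        V=np.array([v1, v2, v3]),
        W_top=np.array([rect.w1, rect.w2]),
        W_end=np.array([rect.w3, rect.w4]),
        member_ids=(instance_id,),
        member_rects=(rect,),
    )


def build_models(
    instances: InstanceSet,
) -> tuple[list[BranchSegmentModel], list[Fork]]:
    """Reduce every instance to its rectangle-based model.

    Segmented instances become initial 3-axis-point models; forked
    instances become center-point forks.  Near-square "segmented"
    rectangles are kept but logged — the sector constraints downstream
    are expected to filter them.
    """
    segments: list[BranchSegmentModel] = []
    forks: list[Fork] = []
    for inst in instances.instances:
        rect = min_area_rect(inst.mask)
        if inst.label == SEGMENTED:
            if rect.aspect < LOW_ASPECT:
                log.warning(
                    "segmented instance %d has low aspect ratio %.2f", inst.id, rect.aspect
                )
            segments.append(model_from_rect(inst.id, rect))
        elif inst.label == FORKED:
            forks.append(Fork(id=inst.id, rect=rect))
        else:  # pragma: no cover - InstanceSet validates labels
            raise ValueError(f"unknown label {inst.label!r}")
    return segments, forks


def dedup(
    segments: list[BranchSegmentModel], iou_threshold: float = 0.15
) -> list[BranchSegmentModel]:
    """Discard duplicated detections by rectangle IoU.

    Pairs are resolved in decreasing-IoU order; in each offending pair
    the smaller-area rectangle is dropped, keeping the more complete
    detection.  Idempotent; survivors' pairwise IoU ≤ threshold.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must be in (0, 1)")
    alive = {s.id: s for s in segments}
    while True:
        worst = None  # (iou, id_a, id_b)
        ids = sorted(alive)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                iou = rect_iou(alive[a].member_rects[0], alive[b].member_rects[0])
                if iou > iou_threshold and (worst is None or iou > worst[0]):
                    worst = (iou, a, b)
        if worst is None:
            break
        _, a, b = worst
        area_a = alive[a].member_rects[0].area
        area_b = alive[b].member_rects[0].area
        drop = b if area_b < area_a or (area_b == area_a and b > a) else a
        log.info("dedup: dropping instance %d (IoU %.3f with %d)",
                 drop, worst[0], a if drop == b else b)
        del alive[drop]
    return [s for s in segments if s.id in alive]
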