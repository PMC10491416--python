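"""Reconstructed branches and their raster rendering."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union

from .geometry import OrientedRect
from .raster import rasterize_geometry


@dataclass(frozen=True)
class BranchChain:
    """A fully reconstructed branch.

    Members are the merged segment instances in top → end order; the
    axis is the merged long-median polyline (fork centers included where
    the chain runs through a bifurcation); the diameter is estimated
    from the member rectangles' short sides.
    """

    id: int
    member_ids: tuple[int, ...]
    fork_ids: tuple[int, ...]
    axis: np.ndarray  # (n, 2)
    member_rects: tuple[OrientedRect, ...]
    fork_rects: tuple[OrientedRect, ...]
    diameter_px: float
    mask: Optional[np.ndarray] = None  # (H, W) bool, set when rendered

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float).reshape(-1, 2))


def chain_polygon(chain: BranchChain, bridge_gaps: bool = True) -> Polygon:
    """Union polygon of the chain: member rectangles, fork rectangles,
    and (optionally) quadrilaterals bridging the gap between consecutive
    members so the rendered branch is a connected region."""
    polys = [r.polygon() for r in chain.member_rects if r.area > 0]
    polys += [r.polygon() for r in chain.fork_rects if r.area > 0]
    if bridge_gaps:
        rects = chain.member_rects
        for a, b in zip(rects[:-1], rects[1:]):
            quad = Polygon([a.w4, a.w3, b.w2, b.w1])
            if not quad.is_valid or quad.area == 0.0:
                quad = MultiPoint([a.w4, a.w3, b.w2, b.w1]).convex_hull
            polys.append(quad)
    if not polys:
        return Polygon()
    return unary_union(polys)


def _bridge_quads(chain: BranchChain) -> list[Polygon]:
    quads = []
    rects = chain.member_rects
    for a, b in zip(rects[:-1], rects[1:]):
        quad = Polygon([a.w4, a.w3, b.w2, b.w1])
        if not quad.is_valid or quad.area == 0.0:
            quad = MultiPoint([a.w4, a.w3, b.w2, b.w1]).convex_hull
        quads.append(quad)
    return quads


def render_chain_mask(
    chain: BranchChain,
    image_size: tuple[int, int],
    bridge_gaps: bool = True,
    instance_masks: Optional[dict[int, np.ndarray]] = None,
) -> np.ndarray:
    """Raster footprint of a reconstructed branch.

    With ``instance_masks`` (id → mask) the footprint is the union of the
    member and fork instances' own masks; otherwise it is the union of
    their minimum bounding rectangles.  Either way, gap-bridging quads
    between consecutive members' facing rectangle edges keep the branch
    a connected region across detection gaps.
    """
    if instance_masks is not None:
        mask = np.zeros(image_size, dtype=bool)
        for iid in chain.member_ids + chain.fork_ids:
            mask |= instance_masks[iid]
        if bridge_gaps:
            for quad in _bridge_quads(chain):
                if not quad.is_empty:
                    mask |= rasterize_geometry(quad, image_size)
        return mask
    return rasterize_geometry(chain_polygon(chain, bridge_gaps), image_size)
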