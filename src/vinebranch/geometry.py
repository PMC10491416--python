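"""Oriented-rectangle and sector-search primitives.

All geometry lives in raster coordinates: 0-based, x to the right, y
downward, pixel centers at integer coordinates.  "Clockwise" therefore
means clockwise as seen on screen, which is the positive shoelace
orientation in this frame.

A branch fragment is replaced by the minimum-area oriented bounding
rectangle of its mask pixels.  The rectangle's corners are labeled
``w1..w4`` clockwise starting from the short edge closest to the upper
left ("top") of the image; the midpoints of the two short edges and the
center give the three points of the long median axis.  Cone-shaped
search regions (sectors) anchored on the axis drive the reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import shapely
from shapely.geometry import LineString, MultiPoint, Point, Polygon

Side = Literal["top", "end"]

_ANGLE_TOL_RAD = 1e-9


# ---------------------------------------------------------------------------
# oriented rectangles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrientedRect:
    """Minimum-area bounding rectangle with normalized corner order.

    ``corners`` holds w1..w4 clockwise (image frame), w1–w2 being the
    "top" short edge and w3–w4 the "end" short edge.  Degenerate
    rectangles (collinear or single-pixel masks) are representable with
    ``short_len`` (and possibly ``long_len``) equal to zero.
    """

    corners: np.ndarray  # (4, 2) float64, [x, y]

    def __post_init__(self) -> None:
        c = np.asarray(self.corners, dtype=float).reshape(4, 2)
        object.__setattr__(self, "corners", c)

    @property
    def w1(self) -> np.ndarray:
        return self.corners[0]

    @property
    def w2(self) -> np.ndarray:
        return self.corners[1]

    @property
    def w3(self) -> np.ndarray:
        return self.corners[2]

    @property
    def w4(self) -> np.ndarray:
        return self.corners[3]

    @property
    def center(self) -> np.ndarray:
        return self.corners.mean(axis=0)

    @property
    def short_len(self) -> float:
        return float(np.linalg.norm(self.corners[1] - self.corners[0]))

    @property
    def long_len(self) -> float:
        return float(np.linalg.norm(self.corners[2] - self.corners[1]))

    @property
    def long_axis_dir(self) -> np.ndarray:
        """Unit vector along the long axis, pointing top → end."""
        v = 0.5 * (self.corners[2] + self.corners[3]) - 0.5 * (
            self.corners[0] + self.corners[1]
        )
        n = np.linalg.norm(v)
        if n == 0.0:
            return np.array([1.0, 0.0])
        return v / n

    @property
    def area(self) -> float:
        return self.short_len * self.long_len

    @property
    def aspect(self) -> float:
        s = self.short_len
        return float("inf") if s == 0.0 else self.long_len / s

    def polygon(self) -> Polygon:
        return Polygon(self.corners)


def min_area_rect(mask: np.ndarray) -> OrientedRect:
    """Minimum-area oriented rectangle enclosing all foreground pixel centers.

    Rotating-calipers over the convex hull (via shapely's
    ``minimum_rotated_rectangle``); degenerate masks (a single pixel or
    a line of pixels) yield rectangles with zero short/long extent.
    """
    ys, xs = np.nonzero(np.asarray(mask))
    if xs.size == 0:
        raise ValueError("min_area_rect: mask has no foreground pixels")
    pts = np.column_stack([xs, ys]).astype(float)
    if xs.size == 1:
        p = pts[0]
        return OrientedRect(np.tile(p, (4, 1)))
    hull = MultiPoint(pts).convex_hull
    mrr = hull.minimum_rotated_rectangle
    return rect_from_shapely(mrr)


def rect_from_shapely(geom) -> OrientedRect:
    """Build an ordered OrientedRect from a shapely rectangle/segment/point."""
    if isinstance(geom, Point):
        p = np.array([geom.x, geom.y])
        return OrientedRect(np.tile(p, (4, 1)))
    if isinstance(geom, LineString):
        a, b = (np.array(c) for c in (geom.coords[0], geom.coords[-1]))
        # zero-width rectangle: top short edge is the endpoint nearer the
        # upper-left, per the ordering convention below
        if (a[1], a[0]) > (b[1], b[0]):
            a, b = b, a
        return OrientedRect(np.array([a, a, b, b]))
    coords = np.asarray(geom.exterior.coords)[:-1]
    if coords.shape[0] != 4:
        raise ValueError(f"expected 4-corner rectangle, got {coords.shape[0]} corners")
    return order_corners(coords)


def rect_from_corners(corners) -> OrientedRect:
    """OrientedRect from 4 corner points in any order."""
    return order_corners(np.asarray(corners, dtype=float).reshape(4, 2))


def order_corners(corners: np.ndarray) -> OrientedRect:
    """Normalize 4 rectangle corners to the w1..w4 labeling convention.

    The "top" short edge is the one whose midpoint has the smaller y
    (tie broken by smaller x, so an exactly horizontal rectangle takes
    its left edge as top); w1→w2 runs along the top edge such that
    w1..w4 is clockwise in image coordinates.  Idempotent.
    """
    c = np.asarray(corners, dtype=float).reshape(4, 2)
    center = c.mean(axis=0)
    d = c - center
    if np.allclose(d, 0.0):
        return OrientedRect(np.tile(center, (4, 1)))
    # ascending atan2 with y down walks the cycle clockwise on screen
    ang = np.arctan2(d[:, 1], d[:, 0])
    cyc = c[np.argsort(ang, kind="stable")]

    def edge_len(i: int) -> float:
        return float(np.linalg.norm(cyc[(i + 1) % 4] - cyc[i]))

    # rotate so edges (0,1) and (2,3) are the short edges
    if edge_len(0) > edge_len(1):
        cyc = np.roll(cyc, -1, axis=0)
    top_mid = 0.5 * (cyc[0] + cyc[1])
    end_mid = 0.5 * (cyc[2] + cyc[3])
    if (end_mid[1], end_mid[0]) < (top_mid[1], top_mid[0]):
        cyc = np.roll(cyc, -2, axis=0)
    return OrientedRect(cyc)


def axis_points(rect: OrientedRect) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three long-median-axis points (v1, v2, v3), top → end."""
    v1 = 0.5 * (rect.w1 + rect.w2)
    v3 = 0.5 * (rect.w3 + rect.w4)
    return v1, rect.center, v3


def rect_iou(a: OrientedRect, b: OrientedRect) -> float:
    """Exact polygon intersection-over-union of two oriented rectangles."""
    pa, pb = a.polygon(), b.polygon()
    if pa.area == 0.0 or pb.area == 0.0:
        return 0.0
    inter = pa.intersection(pb).area
    union = pa.area + pb.area - inter
    return inter / union if union > 0 else 0.0


def angle_between(u, v) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("angle_between: zero-length vector")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# sectors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SectorSpec:
    """A cone-shaped search region: apex, central ray, opening, reach."""

    apex: np.ndarray  # (2,) px
    center_ray: np.ndarray  # (2,) unit vector
    full_angle: float  # degrees, full opening S
    depth: float  # px

    def __post_init__(self) -> None:
        object.__setattr__(self, "apex", np.asarray(self.apex, dtype=float))
        ray = np.asarray(self.center_ray, dtype=float)
        n = np.linalg.norm(ray)
        if n == 0.0:
            raise ValueError("SectorSpec: zero center ray")
        object.__setattr__(self, "center_ray", ray / n)
        if not 0.0 < self.full_angle < 180.0:
            raise ValueError("SectorSpec: full_angle must be in (0, 180)")
        if self.depth <= 0.0:
            raise ValueError("SectorSpec: depth must be positive")


def sector_for(chain, side: Side, depth_factor: float = 3.0) -> SectorSpec:
    """Search sector at one terminal of a branch model/chain.

    Top side: apex v2, boundary rays v2→w1 and v2→w2, central ray v2→v1.
    End side: apex v_{n-1}, rays to w3/w4, central ray v_{n-1}→v_n.  The
    reach is ``depth_factor`` times the local axis window: |v1 v3| at the
    top, |v_{n-2} v_n| at the end.

    ``chain`` needs attributes ``V`` (ordered (n,2) axis points, n ≥ 3),
    ``W_top`` ((2,2): w1, w2) and ``W_end`` ((2,2): w3, w4).
    """
    V = np.asarray(chain.V, dtype=float)
    if V.shape[0] < 3:
        raise ValueError("sector_for: chain needs at least 3 axis points")
    if side == "top":
        apex = V[1]
        rays = np.asarray(chain.W_top, dtype=float) - apex
        center = V[0] - apex
        dis = float(np.linalg.norm(V[0] - V[2]))
    elif side == "end":
        apex = V[-2]
        rays = np.asarray(chain.W_end, dtype=float) - apex
        center = V[-1] - apex
        dis = float(np.linalg.norm(V[-3] - V[-1]))
    else:
        raise ValueError(f"sector_for: unknown side {side!r}")
    full = angle_between(rays[0], rays[1])
    return SectorSpec(apex=apex, center_ray=center, full_angle=full,
                      depth=depth_factor * dis)


def in_sector(spec: SectorSpec, p) -> bool:
    """Inclusive sector membership test.

    True iff the offset angle from the central ray is ≤ S/2 and the
    distance from the apex is ≤ depth.  The apex itself counts as inside.
    """
    p = np.asarray(p, dtype=float)
    d = p - spec.apex
    dist = float(np.linalg.norm(d))
    if dist == 0.0:
        return True
    if dist > spec.depth:
        return False
    ang = angle_between(d, spec.center_ray)
    return ang <= spec.full_angle / 2.0 + np.degrees(_ANGLE_TOL_RAD)
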