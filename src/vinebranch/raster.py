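"""Rasterization helpers.

Masks are boolean rasters indexed ``[y, x]``; a pixel is foreground when
its center (integer coordinates) lies inside or on the boundary of the
source shape.
"""

from __future__ import annotations

import numpy as np
import shapely

_EPS = 1e-9


def rasterize_geometry(geom, image_size: tuple[int, int]) -> np.ndarray:
    """Rasterize a shapely geometry: pixel centers covered by the geometry.

    Boundary-inclusive.  Only the bounding-box window is tested.
    """
    h, w = image_size
    mask = np.zeros((h, w), dtype=bool)
    if geom.is_empty:
        return mask
    minx, miny, maxx, maxy = geom.bounds
    x0 = max(0, int(np.floor(minx)))
    y0 = max(0, int(np.floor(miny)))
    x1 = min(w - 1, int(np.ceil(maxx)))
    y1 = min(h - 1, int(np.ceil(maxy)))
    if x1 < x0 or y1 < y0:
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    inside = shapely.intersects_xy(geom, xs.ravel(), ys.ravel())
    mask[y0:y1 + 1, x0:x1 + 1] = inside.reshape(xs.shape)
    return mask


def rasterize_polygon(coords, image_size: tuple[int, int]) -> np.ndarray:
    """Even-odd polygon fill over pixel centers, boundary-inclusive.

    ``coords`` is an (n, 2) array (or flat COCO-style list) of polygon
    vertices; the ring is closed implicitly.  Even-odd parity makes the
    result well defined for self-intersecting outlines.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(-1, 2)
    if pts.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    h, w = image_size
    mask = np.zeros((h, w), dtype=bool)
    x0 = max(0, int(np.floor(pts[:, 0].min())))
    y0 = max(0, int(np.floor(pts[:, 1].min())))
    x1 = min(w - 1, int(np.ceil(pts[:, 0].max())))
    y1 = min(h - 1, int(np.ceil(pts[:, 1].max())))
    if x1 < x0 or y1 < y0:
        return mask
    gx, gy = np.meshgrid(
        np.arange(x0, x1 + 1, dtype=float), np.arange(y0, y1 + 1, dtype=float)
    )
    px, py = gx.ravel(), gy.ravel()
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    n = pts.shape[0]
    for i in range(n):
        ax, ay = pts[i]
        bx, by = pts[(i + 1) % n]
        # even-odd crossing: edge straddles the horizontal ray at py
        straddle = (ay > py) != (by > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = ax + (py - ay) * (bx - ax) / (by - ay)
        inside ^= straddle & (px < xint)
        # boundary inclusion
        ex, ey = bx - ax, by - ay
        apx, apy = px - ax, py - ay
        cross = ex * apy - ey * apx
        dot = ex * apx + ey * apy
        len2 = ex * ex + ey * ey
        if len2 == 0.0:
            on_edge |= (np.abs(apx) < _EPS) & (np.abs(apy) < _EPS)
        else:
            on_edge |= (
                (np.abs(cross) <= _EPS * max(1.0, np.sqrt(len2)))
                & (dot >= -_EPS)
                & (dot <= len2 + _EPS)
            )
    mask[y0:y1 + 1, x0:x1 + 1] = (inside | on_edge).reshape(gx.shape)
    return mask


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Pixel IoU of two boolean masks on the same canvas."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)
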