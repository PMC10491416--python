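"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from vinebranch.geometry import OrientedRect, rect_from_corners
from vinebranch.masks_io import FORKED, SEGMENTED, Instance, InstanceSet
from vinebranch.raster import rasterize_polygon


def quad_corners(cx: float, cy: float, length: float, width: float, phi: float) -> np.ndarray:
    """Corners of an oriented rectangle; phi is the long-axis angle
    measured from straight down (+y), positive toward +x."""
    c = np.array([cx, cy], dtype=float)
    d = np.array([np.sin(phi), np.cos(phi)])
    n = np.array([d[1], -d[0]])
    return np.array(
        [
            c - d * length / 2 - n * width / 2,
            c - d * length / 2 + n * width / 2,
            c + d * length / 2 + n * width / 2,
            c + d * length / 2 - n * width / 2,
        ]
    )


def quad_rect(cx, cy, length, width, phi) -> OrientedRect:
    return rect_from_corners(quad_corners(cx, cy, length, width, phi))


def quad_mask(shape, cx, cy, length, width, phi) -> np.ndarray:
    return rasterize_polygon(quad_corners(cx, cy, length, width, phi).ravel().tolist(), shape)


def make_instance(iid, shape, cx, cy, length, width, phi, label=SEGMENTED) -> Instance:
    return Instance(id=iid, label=label, mask=quad_mask(shape, cx, cy, length, width, phi))


def make_scene(shape, specs) -> InstanceSet:
    """InstanceSet from (id, label, cx, cy, length, width, phi) tuples."""
    instances = [
        make_instance(iid, shape, cx, cy, length, width, phi, label)
        for iid, label, cx, cy, length, width, phi in specs
    ]
    return InstanceSet(image_size=shape, instances=tuple(instances))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


__all__ = [
    "quad_corners",
    "quad_rect",
    "quad_mask",
    "make_instance",
    "make_scene",
    "SEGMENTED",
    "FORKED",
]
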