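"""Seeded generator of synthetic vine scenes with ground truth.

A scene emulates what an instance-segmentation model emits for a trellis
of vine-like branches: each branch is a smooth curve (heading random
walk with a bounded per-step turn) of constant width, annotated as a
string of quadrilateral "segmented branch" instances with long/short
aspect ratio in [2, 4] — shorter quads where the curve bends — plus
near-square "forked branch" instances at bifurcations.  Detection
pathologies are injected on top: per-segment dropout (missed
detections), jittered duplicate masks that overlap their source above
the 0.15 de-duplication threshold, and small low-aspect distractor
blobs standing in for falsely detected leaves and petioles.

Branches are laid out in disjoint vertical corridors, growing downward
with bounded wander, so that ground-truth chains are unambiguous;
distractors are rejection-sampled away from every branch and from the
terminal search cones so that they stay isolated single instances.

Aspect ratios are defined on the rasterized instance (the ratio of the
pixel-center extents that the minimum-bounding-rectangle step measures).
Everything is a pure function of the spec, including its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .masks_io import FORKED, SEGMENTED, Instance, InstanceSet
from .raster import rasterize_polygon


@dataclass(frozen=True)
class SceneSpec:
    image_size: tuple[int, int] = (720, 1280)  # (H, W)
    n_branches: int = 5
    segments_range: tuple[int, int] = (4, 8)  # per branch, inclusive
    curvature_scale: float = 0.10  # rad per segment step
    branch_width_range: tuple[float, float] = (9.0, 20.0)  # px
    fork_probability: float = 0.25
    segment_aspect_range: tuple[float, float] = (2.0, 4.0)
    gap_range: tuple[float, float] = (1.0, 3.0)  # px between quads
    dropout_rate: float = 0.0
    duplicate_rate: float = 0.0
    distractor_count: int = 3
    mask_noise: float = 0.0  # px std of corner jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_branches < 1:
            raise ValueError("n_branches must be at least 1")
        if not (1 <= self.segments_range[0] <= self.segments_range[1]):
            raise ValueError("segments_range must satisfy 1 <= lo <= hi")
        if self.curvature_scale < 0.0:
            raise ValueError("curvature_scale must be non-negative")
        for name in ("branch_width_range", "gap_range"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi")
        lo, hi = self.segment_aspect_range
        if not (1.0 < lo <= hi):
            raise ValueError("segment_aspect_range must satisfy 1 < lo <= hi")
        for rate in (self.dropout_rate, self.duplicate_rate, self.fork_probability):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        h, w = self.image_size
        if self.branch_width_range[1] > min(h, w):
            raise ValueError("branch width exceeds the image size")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows about the scene it drew."""

    branch_of: dict[int, int]  # instance id -> branch id (-1: distractor)
    branch_masks: dict[int, np.ndarray]  # branch id -> full-branch mask
    branch_members: dict[int, tuple[int, ...]]  # branch id -> instance ids (forks shared)
    diameters: dict[int, float]  # branch id -> true width, px
    fork_positions: dict[int, tuple[float, float]]  # fork instance id -> center
    polygons: dict[int, np.ndarray]  # instance id -> drawn outline corners
    duplicate_ids: frozenset[int] = field(default_factory=frozenset)
    distractor_ids: frozenset[int] = field(default_factory=frozenset)
    dropped_ids: frozenset[int] = field(default_factory=frozenset)

    @property
    def n_branches(self) -> int:
        return len(self.branch_masks)


def _quad(p: np.ndarray, d: np.ndarray, length: float, width: float,
          jitter: Optional[np.ndarray] = None) -> np.ndarray:
    """Rectangle corners starting at p, running `length` along unit d."""
    n = np.array([-d[1], d[0]])
    half = 0.5 * width * n
    corners = np.array([p - half, p + half, p + length * d + half, p + length * d - half])
    if jitter is not None:
        corners = corners + jitter
    return corners


def _dir(phi: float) -> np.ndarray:
    # heading measured from straight down (+y); positive tilts right
    return np.array([math.sin(phi), math.cos(phi)])


class _Builder:
    def __init__(self, spec: SceneSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.h, self.w = spec.image_size
        self.instances: list[tuple[int, str, np.ndarray]] = []  # id, label, mask
        self.branch_of: dict[int, int] = {}
        self.polygons: dict[int, np.ndarray] = {}
        self.branch_members: dict[int, list[int]] = {}
        self.branch_instance_masks: dict[int, list[np.ndarray]] = {}
        self.diameters: dict[int, float] = {}
        self.fork_positions: dict[int, tuple[float, float]] = {}
        self.quad_centers: list[np.ndarray] = []
        self.next_id = 0
        self.next_branch = 0

    def _emit(self, label: str, corners: np.ndarray, branch: int) -> int:
        mask = rasterize_polygon(corners, (self.h, self.w))
        iid = self.next_id
        self.next_id += 1
        self.instances.append((iid, label, mask))
        self.branch_of[iid] = branch
        self.polygons[iid] = np.asarray(corners, dtype=float)
        if branch >= 0:
            self.branch_instance_masks.setdefault(branch, []).append(mask)
            self.branch_members.setdefault(branch, []).append(iid)
        self.quad_centers.append(corners.mean(axis=0))
        return iid

    def _in_bounds(self, corners: np.ndarray, margin: float = 2.0) -> bool:
        return (
            corners[:, 0].min() >= margin
            and corners[:, 0].max() <= self.w - 1 - margin
            and corners[:, 1].min() >= margin
            and corners[:, 1].max() <= self.h - 1 - margin
        )

    def _jitter(self) -> Optional[np.ndarray]:
        if self.spec.mask_noise <= 0.0:
            return None
        return self.rng.normal(0.0, self.spec.mask_noise, size=(4, 2))

    def _walk(
        self,
        branch: int,
        p: np.ndarray,
        phi: float,
        width: float,
        n_segments: int,
        corridor: tuple[float, float],
        fork_after: Optional[int] = None,
    ) -> tuple[np.ndarray, float, Optional[tuple[np.ndarray, float, float]]]:
        """Lay quads along a random-walk curve; returns the final point,
        heading, and the fork anchor (center, heading, side) if placed."""
        spec = self.spec
        rng = self.rng
        fork_anchor = None
        start = np.array(p, dtype=float)
        phi0 = phi
        # the per-step heading change stays below the narrowest sector
        # half-angle (arctan(1/4) ~ 14 deg), so consecutive quads of one
        # branch always satisfy the search constraints
        max_turn = min(0.18, 1.5 * spec.curvature_scale)
        aspect = 0.5 * (spec.segment_aspect_range[0] + spec.segment_aspect_range[1])
        for k in range(n_segments):
            aspect = rng.uniform(*spec.segment_aspect_range)
            # high local curvature -> shorter quad (tighter fit to the curve)
            turn = rng.uniform(-spec.curvature_scale, spec.curvature_scale)
            aspect = max(spec.segment_aspect_range[0],
                         aspect - abs(turn) / max(spec.curvature_scale, 1e-9))
            length = aspect * (width - 1.0) + 1.0
            d = _dir(phi)
            corners = _quad(p, d, length, width, self._jitter())
            if not self._in_bounds(corners):
                break
            self._emit(SEGMENTED, corners, branch)
            gap = rng.uniform(*spec.gap_range)
            p = p + (length + gap) * d
            if fork_after is not None and k == fork_after:
                side = 1.1 * width
                fd = _dir(phi)
                fcorners = _quad(p, fd, side, width, self._jitter())
                if self._in_bounds(fcorners):
                    fid = self._emit(FORKED, fcorners, branch)
                    center = p + 0.5 * side * fd  # nominal center, jitter aside
                    self.fork_positions[fid] = (float(center[0]), float(center[1]))
                    # lateral limbs start at the fork center so the fork lies
                    # on their long axis
                    fork_anchor = (center.copy(), phi, side)
                    p = p + (side + rng.uniform(*spec.gap_range)) * fd
            # gentle steering: drift back toward the corridor, and keep the
            # heading within a moderate fan of the branch's initial heading
            lo, hi = corridor
            if p[0] < lo:
                turn += 0.6 * max_turn
            elif p[0] > hi:
                turn -= 0.6 * max_turn
            phi_target = float(np.clip(phi + turn, phi0 - 0.45, phi0 + 0.45))
            phi = phi + float(np.clip(phi_target - phi, -max_turn, max_turn))
        return p, phi, fork_anchor

    def build_branches(self) -> None:
        spec = self.spec
        rng = self.rng
        slot = self.w / spec.n_branches
        for b in range(spec.n_branches):
            width = rng.uniform(*spec.branch_width_range)
            n_seg = int(rng.integers(spec.segments_range[0], spec.segments_range[1] + 1))
            cx = (b + 0.5) * slot + rng.uniform(-0.1, 0.1) * slot
            corridor = ((b + 0.12) * slot + width, (b + 0.88) * slot - width)
            start = np.array([cx, rng.uniform(25.0, 45.0)])
            phi = rng.uniform(-0.2, 0.2)
            fork_after = None
            if n_seg >= 4 and rng.random() < spec.fork_probability:
                fork_after = int(rng.integers(1, n_seg - 2))
            branch = self.next_branch
            self.next_branch += 1
            self.diameters[branch] = width
            _, _, fork_anchor = self._walk(
                branch, start, phi, width, n_seg, corridor, fork_after
            )
            if fork_anchor is not None:
                # lateral limb: its own ground-truth branch, sharing the fork
                fcenter, fphi, side = fork_anchor
                fork_iid = max(self.fork_positions)
                lat_width = max(spec.branch_width_range[0] * 0.8, 0.75 * width)
                toward_center = 1.0 if fcenter[0] < self.w / 2 else -1.0
                lat_phi = fphi + toward_center * rng.uniform(0.55, 0.95)
                lat_start = fcenter + (0.5 * side + rng.uniform(*spec.gap_range)) * _dir(lat_phi)
                lat_branch = self.next_branch
                self.next_branch += 1
                self.diameters[lat_branch] = lat_width
                n_lat = int(rng.integers(2, 4))
                self._walk(lat_branch, lat_start, lat_phi, lat_width, n_lat,
                           corridor=(0.0 + lat_width, self.w - 1.0 - lat_width))
                if lat_branch in self.branch_members:
                    # the fork instance belongs to both adjoining branches
                    fork_mask = next(m for i, _, m in self.instances if i == fork_iid)
                    self.branch_instance_masks[lat_branch].append(fork_mask)
                    self.branch_members[lat_branch].append(fork_iid)
                else:  # limb fell outside the canvas: no such branch
                    del self.diameters[lat_branch]

    def place_distractors(self) -> frozenset[int]:
        """Scatter leaf/petiole stand-ins that are singletons by construction.

        Each placement is rejection-sampled against the pipeline's own
        linking predicates: a candidate is discarded if it could be
        captured by (or capture) any branch segment or previously placed
        distractor, either through the primary sector search or through
        the relaxed free connection.  Deduplication never touches them
        because they also keep a 70 px center clearance.
        """
        from .config import Config
        from .geometry import rect_from_corners
        from .reconstruct import find_candidates
        from .secondary import _free_link
        from .segments import model_from_rect

        spec = self.spec
        rng = self.rng
        cfg = Config()

        def could_link(a, b) -> bool:
            for side in ("top", "end"):
                if find_candidates(a, side, [b], [], cfg):
                    return True
                if find_candidates(b, side, [a], [], cfg):
                    return True
            return (_free_link(a, b, cfg) is not None
                    or _free_link(b, a, cfg) is not None)

        scene_models = [
            model_from_rect(iid, rect_from_corners(self.polygons[iid]))
            for iid, label, _ in self.instances
            if label == SEGMENTED
        ]
        ids = []
        centers = np.array(self.quad_centers) if self.quad_centers else np.zeros((0, 2))
        probe_id = -1
        for _ in range(spec.distractor_count):
            best = None
            for _attempt in range(300):
                side = rng.uniform(6.0, 14.0)
                aspect = rng.uniform(1.0, 1.6)
                theta = rng.uniform(0.0, math.pi)
                c = np.array([
                    rng.uniform(20.0, self.w - 21.0),
                    rng.uniform(20.0, self.h - 21.0),
                ])
                dmin = (
                    float(np.min(np.linalg.norm(centers - c, axis=1)))
                    if len(centers) else np.inf
                )
                if dmin < 70.0:
                    continue
                d = np.array([math.cos(theta), math.sin(theta)])
                corners = _quad(c - 0.5 * aspect * side * d, d, aspect * side, side)
                if not self._in_bounds(corners):
                    continue
                probe_id -= 1
                cand = model_from_rect(probe_id, rect_from_corners(corners))
                if any(could_link(cand, m) for m in scene_models):
                    continue
                best = corners
                break
            if best is None:
                continue  # crowded scene: fewer distractors than requested
            iid = self._emit(SEGMENTED, best, -1)
            scene_models.append(model_from_rect(iid, rect_from_corners(best)))
            centers = np.array(self.quad_centers)
            ids.append(iid)
        return frozenset(ids)


def save_ground_truth(
    truth: GroundTruth, path, image_size: tuple[int, int]
) -> None:
    """Serialize the ground truth as JSON (branch outlines, not rasters)."""
    import json

    doc = {
        "image_size": [int(s) for s in image_size],
        "branches": [
            {
                "id": int(b),
                "diameter_px": float(truth.diameters[b]),
                "polygons": [
                    [float(v) for v in truth.polygons[i].ravel()]
                    for i in truth.branch_members[b]
                ],
            }
            for b in sorted(truth.branch_masks)
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_ground_truth(path) -> tuple[dict[int, np.ndarray], dict[int, float], tuple[int, int]]:
    """Re-render branch masks and diameters from a ground-truth JSON."""
    import json

    with open(path) as fh:
        doc = json.load(fh)
    h, w = doc["image_size"]
    masks: dict[int, np.ndarray] = {}
    diameters: dict[int, float] = {}
    for entry in doc["branches"]:
        mask = np.zeros((h, w), dtype=bool)
        for ring in entry["polygons"]:
            mask |= rasterize_polygon(ring, (h, w))
        masks[entry["id"]] = mask
        diameters[entry["id"]] = entry["diameter_px"]
    return masks, diameters, (h, w)


def generate_scene(spec: SceneSpec) -> tuple[InstanceSet, GroundTruth]:
    """Draw one scene; fully deterministic given ``spec`` (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    b = _Builder(spec, rng)
    b.build_branches()

    # ground-truth branch masks: union of the branch's instances, before dropout
    branch_masks = {
        br: np.logical_or.reduce(masks)
        for br, masks in sorted(b.branch_instance_masks.items())
    }

    # dropout: each segmented instance may be missed by the detector
    dropped: set[int] = set()
    if spec.dropout_rate > 0.0:
        for iid, label, _ in b.instances:
            if label == SEGMENTED and rng.random() < spec.dropout_rate:
                dropped.add(iid)

    # duplicates: jittered, slightly shrunken re-detections of kept segments
    duplicates: set[int] = set()
    new_instances = []
    for iid, label, mask in b.instances:
        if iid in dropped:
            continue
        new_instances.append((iid, label, mask))
        if label == SEGMENTED and spec.duplicate_rate > 0.0 and rng.random() < spec.duplicate_rate:
            ys, xs = np.nonzero(mask)
            c = np.array([xs.mean(), ys.mean()])
            shift = rng.uniform(-2.0, 2.0, size=2)
            dup_poly = (b.polygons[iid] - c) * 0.9 + c + shift
            dup = rasterize_polygon(dup_poly, spec.image_size)
            if not dup.any():
                continue
            did = b.next_id
            b.next_id += 1
            new_instances.append((did, SEGMENTED, dup))
            b.branch_of[did] = b.branch_of[iid]
            b.polygons[did] = dup_poly
            duplicates.add(did)
    b.instances = new_instances

    distractor_ids = b.place_distractors()

    instance_set = InstanceSet(
        image_size=spec.image_size,
        instances=tuple(
            Instance(id=iid, label=label, mask=mask) for iid, label, mask in b.instances
        ),
    )
    truth = GroundTruth(
        branch_of=dict(b.branch_of),
        branch_masks=branch_masks,
        branch_members={k: tuple(v) for k, v in sorted(b.branch_members.items())},
        diameters=dict(b.diameters),
        fork_positions=dict(b.fork_positions),
        polygons=dict(b.polygons),
        duplicate_ids=frozenset(duplicates),
        distractor_ids=distractor_ids,
        dropped_ids=frozenset(dropped),
    )
    return instance_set, truth
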