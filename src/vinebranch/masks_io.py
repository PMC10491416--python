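"""Reading instance masks and writing reconstruction results.

Two input formats are accepted:

``png_dir``
    A directory of per-instance binary PNG masks plus a manifest
    (``manifest.yaml`` or ``manifest.json``) mapping each filename to its
    class label (``segmented`` or ``forked``).

``polygon_json``
    A single JSON document in the COCO-polygon dialect::

        {"image_size": [H, W],
         "instances": [{"id": 0, "category": "segmented",
                        "polygon": [x1, y1, x2, y2, ...]}, ...]}

    ``segmentation`` (a list of flat rings) is accepted as an alias for
    ``polygon``; rings are filled with the even-odd rule over pixel
    centers, boundary-inclusive.

Results are written as one JSON document per scene plus an optional
color overlay PNG with one color per reconstructed branch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .chains import BranchChain, render_chain_mask
from .geometry import rect_from_corners
from .raster import rasterize_polygon

log = logging.getLogger(__name__)

SEGMENTED = "segmented"
FORKED = "forked"
_LABELS = {SEGMENTED, FORKED}


@dataclass(frozen=True)
class Instance:
    id: int
    label: str
    mask: np.ndarray  # (H, W) bool

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise ValueError(f"instance {self.id}: unknown label {self.label!r}")
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


@dataclass(frozen=True)
class InstanceSet:
    """All detected instances of one scene."""

    image_size: tuple[int, int]  # (H, W)
    instances: tuple[Instance, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "instances", tuple(self.instances))
        h, w = self.image_size
        ids = [i.id for i in self.instances]
        if len(ids) != len(set(ids)):
            raise ValueError("instance ids must be unique")
        for inst in self.instances:
            if inst.mask.shape != (h, w):
                raise ValueError(
                    f"instance {inst.id}: mask shape {inst.mask.shape} != image size {(h, w)}"
                )
            if not inst.mask.any():
                raise ValueError(f"instance {inst.id}: empty mask")

    def __len__(self) -> int:
        return len(self.instances)


def _filtered_instance_set(image_size, raw: list[Instance]) -> InstanceSet:
    kept = []
    for inst in raw:
        if inst.mask.any():
            kept.append(inst)
        else:
            log.warning("dropping instance %d: empty mask", inst.id)
    return InstanceSet(image_size=tuple(image_size), instances=tuple(kept))


def load_instances(path: str | Path, format: str = "png_dir") -> InstanceSet:
    """Load a scene's instances from ``png_dir`` or ``polygon_json``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "png_dir":
        return _load_png_dir(path)
    if format == "polygon_json":
        return _load_polygon_json(path)
    raise ValueError(f"unknown format {format!r}")


def _load_manifest(directory: Path) -> dict:
    for name in ("manifest.yaml", "manifest.yml", "manifest.json"):
        p = directory / name
        if p.exists():
            with open(p) as fh:
                if p.suffix == ".json":
                    return json.load(fh)
                return yaml.safe_load(fh)
    raise FileNotFoundError(f"no manifest.yaml/manifest.json in {directory}")


def _load_png_dir(directory: Path) -> InstanceSet:
    manifest = _load_manifest(directory)
    pngs = sorted(p.name for p in directory.glob("*.png"))
    for name in pngs:
        if name not in manifest:
            raise KeyError(f"mask file {name!r} has no manifest entry")
    raw: list[Instance] = []
    image_size = None
    for idx, name in enumerate(pngs):
        label = manifest[name]
        arr = np.asarray(Image.open(directory / name).convert("L")) > 0
        if image_size is None:
            image_size = arr.shape
        elif arr.shape != image_size:
            raise ValueError(f"mask {name!r} shape {arr.shape} != {image_size}")
        raw.append(Instance(id=idx, label=label, mask=arr))
    missing = set(manifest) - set(pngs)
    if missing:
        raise FileNotFoundError(
            f"manifest entries without mask files: {', '.join(sorted(missing))}"
        )
    if image_size is None:
        raise ValueError(f"no PNG masks found in {directory}")
    return _filtered_instance_set(image_size, raw)


def _load_polygon_json(path: Path) -> InstanceSet:
    with open(path) as fh:
        doc = json.load(fh)
    h, w = doc["image_size"]
    raw: list[Instance] = []
    for k, entry in enumerate(doc["instances"]):
        label = entry["category"]
        inst_id = int(entry.get("id", k))
        rings = entry.get("segmentation")
        if rings is None:
            rings = [entry["polygon"]]
        mask = np.zeros((h, w), dtype=bool)
        for ring in rings:
            mask |= rasterize_polygon(ring, (h, w))
        raw.append(Instance(id=inst_id, label=label, mask=mask))
    return _filtered_instance_set((h, w), raw)


def save_instances(
    instances: InstanceSet,
    path: str | Path,
    format: str = "png_dir",
    polygons: dict[int, "np.ndarray"] | None = None,
) -> None:
    """Write a scene in one of the two accepted input formats.

    ``polygon_json`` needs the instance outlines (id → (n, 2) corner
    array); ``png_dir`` writes one binary PNG per instance plus the
    label manifest.
    """
    path = Path(path)
    if format == "png_dir":
        path.mkdir(parents=True, exist_ok=True)
        manifest = {}
        for inst in instances.instances:
            name = f"instance_{inst.id:04d}.png"
            Image.fromarray(inst.mask.astype(np.uint8) * 255).save(path / name)
            manifest[name] = inst.label
        with open(path / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh)
    elif format == "polygon_json":
        if polygons is None:
            raise ValueError("polygon_json output needs instance outlines")
        doc = {
            "image_size": [int(s) for s in instances.image_size],
            "instances": [
                {
                    "id": int(inst.id),
                    "category": inst.label,
                    "polygon": [float(v) for v in np.asarray(polygons[inst.id]).ravel()],
                }
                for inst in instances.instances
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def _rect_corners(rect) -> list[list[float]]:
    return [[float(x), float(y)] for x, y in rect.corners]


def save_chains(
    chains: list[BranchChain], path: str | Path, image_size: tuple[int, int]
) -> None:
    """Write the per-scene reconstruction result as JSON."""
    doc = {
        "image_size": [int(image_size[0]), int(image_size[1])],
        "chains": [
            {
                "id": int(c.id),
                "member_ids": [int(i) for i in c.member_ids],
                "fork_ids": [int(i) for i in c.fork_ids],
                "axis": [[float(x), float(y)] for x, y in c.axis],
                "diameter_px": float(c.diameter_px),
                "member_rects": [_rect_corners(r) for r in c.member_rects],
                "fork_rects": [_rect_corners(r) for r in c.fork_rects],
            }
            for c in chains
        ],
    }
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_chains(path: str | Path) -> tuple[list[BranchChain], tuple[int, int]]:
    """Inverse of :func:`save_chains` (masks are not re-rendered)."""
    with open(path) as fh:
        doc = json.load(fh)
    chains = [
        BranchChain(
            id=entry["id"],
            member_ids=tuple(entry["member_ids"]),
            fork_ids=tuple(entry["fork_ids"]),
            axis=np.asarray(entry["axis"], dtype=float).reshape(-1, 2),
            member_rects=tuple(rect_from_corners(r) for r in entry["member_rects"]),
            fork_rects=tuple(rect_from_corners(r) for r in entry["fork_rects"]),
            diameter_px=entry["diameter_px"],
        )
        for entry in doc["chains"]
    ]
    return chains, tuple(doc["image_size"])


_PALETTE = np.array(
    [
        (230, 25, 75), (60, 180, 75), (255, 225, 25), (0, 130, 200),
        (245, 130, 48), (145, 30, 180), (70, 240, 240), (240, 50, 230),
        (210, 245, 60), (250, 190, 212), (0, 128, 128), (220, 190, 255),
        (170, 110, 40), (255, 250, 200), (128, 0, 0), (170, 255, 195),
    ],
    dtype=np.uint8,
)


def render_overlay(
    chains: list[BranchChain], image_size: tuple[int, int]
) -> np.ndarray:
    """Color raster with each reconstructed branch painted distinctly."""
    h, w = image_size
    img = np.zeros((h, w, 3), dtype=np.uint8)
    for k, chain in enumerate(chains):
        mask = chain.mask if chain.mask is not None else render_chain_mask(chain, (h, w))
        img[mask] = _PALETTE[k % len(_PALETTE)]
    return img


def save_overlay(
    chains: list[BranchChain], path: str | Path, image_size: tuple[int, int]
) -> None:
    Image.fromarray(render_overlay(chains, image_size)).save(path)
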