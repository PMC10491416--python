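"""Tunable parameters of the reconstruction pipeline.

Every constant of the method is surfaced here so the pipeline can be
re-tuned for other crops without touching code.  The defaults are the
operating point used throughout: duplicate rectangles are discarded
above IoU 0.15, segment/fork search reach is 3x / 1.6x the local axis
length, the relaxed second-pass reach is 5x, chains meeting at a
bifurcation are joined when their interior angle exceeds 100 degrees,
and a reconstructed branch counts as correct above mask IoU 0.9.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class Config:
    iou_dedup: float = 0.15
    depth_factor_segment: float = 3.0
    depth_factor_fork: float = 1.6
    free_depth_factor: float = 5.0
    bifurcation_angle_deg: float = 100.0
    correct_branch_iou: float = 0.9
    match_iou: float = 0.5
    prune_isolated: bool = True
    secondary_connection: bool = True
    bridge_gaps: bool = True
    render_mode: str = "masks"  # "masks": union of member masks; "rects": rectangles

    def __post_init__(self) -> None:
        if self.render_mode not in ("masks", "rects"):
            raise ValueError(f"render_mode must be 'masks' or 'rects', got {self.render_mode!r}")

    def replace(self, **kwargs) -> "Config":
        _check_keys(kwargs)
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        _check_keys(d)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELDS = {f.name for f in dataclasses.fields(Config)}


def _check_keys(d: dict) -> None:
    unknown = set(d) - _FIELDS
    if unknown:
        raise KeyError(f"unknown config key(s): {', '.join(sorted(unknown))}")
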