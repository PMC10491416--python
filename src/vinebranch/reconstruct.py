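"""Bidirectional sector search: the primary chain-growing pass.

Every segment model carries two search sectors along its long axis: a
"top" sector opening toward the upper/left terminal and an "end" sector
opening toward the lower/right terminal.  A candidate segment is
accepted when its facing terminal axis point falls inside the sector
(offset angle D ≤ S/2, distance ≤ 3·dis) *and* the reverse check holds:
looking back from the candidate, the two long axes must be aligned
within the same half-angle (O ≤ S/2), which rejects captures across
neighboring branches.  A fork qualifies when its center point falls in
the sector at the tighter reach 1.6·dis.  The nearest qualifying
candidate is merged; merging a fork closes that side of the chain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping

import numpy as np

from .config import Config
from .geometry import Side, angle_between, in_sector, sector_for
from .segments import BranchSegmentModel, Fork


@dataclass(frozen=True)
class CandidateMark:
    """A candidate accepted into a search sector."""

    candidate_id: int
    side: Side
    kind: Literal["segment", "fork"]
    distance: float  # px, terminal point to facing point / fork center
    passed_reverse_check: bool


def find_candidates(
    target: BranchSegmentModel,
    side: Side,
    segments: Iterable[BranchSegmentModel],
    forks: Iterable[Fork],
    config: Config = Config(),
) -> list[CandidateMark]:
    """Mark all segments and forks inside the target's search sector.

    ``segments`` must not contain the target itself nor members already
    merged into it.  Segment candidates are tested at their facing
    terminal axis point (t_n for the top side, t_1 for the end side) and
    must pass the reverse alignment check; forks are tested at their
    center with the shorter fork reach.
    """
    seg_sector = sector_for(target, side, config.depth_factor_segment)
    fork_sector = sector_for(target, side, config.depth_factor_fork)
    terminal = target.V[0] if side == "top" else target.V[-1]
    half_angle = seg_sector.full_angle / 2.0

    marks: list[CandidateMark] = []
    for cand in segments:
        if cand.id == target.id:
            continue
        if side == "top":
            facing = cand.V[-1]
            facing_dir = cand.V[-2] - cand.V[-1]  # t_n -> t_{n-1}
        else:
            facing = cand.V[0]
            facing_dir = cand.V[1] - cand.V[0]  # t_1 -> t_2
        if not in_sector(seg_sector, facing):
            continue
        # reverse check: candidate axis must align with the target's
        reverse_ok = angle_between(seg_sector.center_ray, facing_dir) <= half_angle
        if not reverse_ok:
            continue
        marks.append(
            CandidateMark(
                candidate_id=cand.id,
                side=side,
                kind="segment",
                distance=float(np.linalg.norm(terminal - facing)),
                passed_reverse_check=True,
            )
        )
    for fork in forks:
        if in_sector(fork_sector, fork.center):
            marks.append(
                CandidateMark(
                    candidate_id=fork.id,
                    side=side,
                    kind="fork",
                    distance=float(np.linalg.norm(terminal - fork.center)),
                    passed_reverse_check=True,
                )
            )
    return marks


def merge(
    target: BranchSegmentModel,
    mark: CandidateMark,
    registry: Mapping[int, BranchSegmentModel | Fork],
) -> BranchSegmentModel:
    """Merge a marked candidate into the target chain.

    A segment is concatenated onto the marked side (axis points, member
    lists and that side's boundary corners are taken over); a fork is
    recorded as the side's terminal bifurcation, closing the side.
    """
    if target.side_closed(mark.side):
        raise ValueError(f"cannot merge onto closed side {mark.side!r}")
    cand = registry[mark.candidate_id]
    if mark.kind == "fork":
        assert isinstance(cand, Fork)
        return target.with_fork(mark.side, cand)
    assert isinstance(cand, BranchSegmentModel)
    if mark.side == "top":
        return replace(
            target,
            V=np.vstack([cand.V, target.V]),
            W_top=cand.W_top,
            member_ids=cand.member_ids + target.member_ids,
            member_rects=cand.member_rects + target.member_rects,
            top_fork=cand.top_fork,
            interior_forks=cand.interior_forks + target.interior_forks,
        )
    return replace(
        target,
        V=np.vstack([target.V, cand.V]),
        W_end=cand.W_end,
        member_ids=target.member_ids + cand.member_ids,
        member_rects=target.member_rects + cand.member_rects,
        end_fork=cand.end_fork,
        interior_forks=target.interior_forks + cand.interior_forks,
    )


def reconstruct(
    segments: list[BranchSegmentModel],
    forks: list[Fork],
    config: Config = Config(),
) -> list[BranchSegmentModel]:
    """Grow chains greedily from every unconsumed segment.

    Seeds are processed largest-rectangle-first.  For the current chain
    the two sides alternate (top, then end); on each visit the nearest
    qualifying candidate is merged (ties broken by candidate id).  A
    consumed segment never joins a second chain; forks are junctions and
    may terminate several chains.
    """
    unconsumed = {s.id: s for s in segments}
    registry: dict[int, BranchSegmentModel | Fork] = {s.id: s for s in segments}
    registry.update({f.id: f for f in forks})
    seed_order = sorted(
        segments, key=lambda s: (-s.member_rects[0].area, s.id)
    )
    chains: list[BranchSegmentModel] = []
    for seed in seed_order:
        if seed.id not in unconsumed:
            continue
        del unconsumed[seed.id]
        chain = seed
        progress = True
        while progress:
            progress = False
            for side in ("top", "end"):
                if chain.side_closed(side):
                    continue
                marks = find_candidates(
                    chain, side, unconsumed.values(), forks, config
                )
                if not marks:
                    continue
                best = min(marks, key=lambda m: (m.distance, m.candidate_id))
                chain = merge(chain, best, registry)
                if best.kind == "segment":
                    del unconsumed[best.candidate_id]
                progress = True
        chains.append(chain)
    return chains
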