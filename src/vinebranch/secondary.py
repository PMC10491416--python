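"""Second connection pass and full scene pipeline.

The primary sector search stops a chain whenever it reaches a fork, so a
real branch running straight through a bifurcation is split into a
"main" chain (fork at its tail) and "secondary" chains (fork at their
head).  This pass re-joins them when the interior angle at the fork says
the pair continues the same branch (straight ≈ 180°, side limb ≈ 90°;
threshold 100°).  Chains split by missed detections or occlusion — with
no shared fork — are joined by a relaxed sector search (double opening
angle, 5x reach) guarded by a deflection constraint that rejects
parallel neighboring branches.  Finally, single-segment chains with no
fork are pruned: isolated fragments are overwhelmingly leaf/petiole
false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Optional

import numpy as np

from .chains import BranchChain, render_chain_mask
from .config import Config
from .geometry import angle_between, sector_for
from .masks_io import InstanceSet
from .metrics import chain_diameter
from .reconstruct import reconstruct
from .segments import BranchSegmentModel, Fork, build_models, dedup


@dataclass(frozen=True)
class ForkGroup:
    """Chains meeting at one bifurcation.

    The chain whose tail node is the fork is a main branch; a chain
    whose head (top) node is the fork is a secondary branch.
    """

    fork: Fork
    main_chains: tuple[BranchSegmentModel, ...]
    secondary_chains: tuple[BranchSegmentModel, ...]


def fork_groups(chains: list[BranchSegmentModel]) -> list[ForkGroup]:
    by_fork: dict[int, dict] = {}
    for c in chains:
        if c.end_fork is not None:
            by_fork.setdefault(c.end_fork.id, {"fork": c.end_fork, "m": [], "s": []})["m"].append(c)
        if c.top_fork is not None:
            by_fork.setdefault(c.top_fork.id, {"fork": c.top_fork, "m": [], "s": []})["s"].append(c)
    return [
        ForkGroup(fork=v["fork"], main_chains=tuple(v["m"]), secondary_chains=tuple(v["s"]))
        for _, v in sorted(by_fork.items())
    ]


def _bifurcation_angle(main: BranchSegmentModel, sec: BranchSegmentModel, fork: Fork) -> float:
    """Interior angle at the fork between the two chains' near-terminal
    axis points; 180° for a straight continuation, 90° for a
    perpendicular side branch."""
    u = main.V[-2] - fork.center
    v = sec.V[1] - fork.center
    return angle_between(u, v)


def _merge_through_fork(
    main: BranchSegmentModel, sec: BranchSegmentModel, fork: Fork
) -> BranchSegmentModel:
    return BranchSegmentModel(
        id=main.id,
        V=np.vstack([main.V, fork.center[None, :], sec.V]),
        W_top=main.W_top,
        W_end=sec.W_end,
        member_ids=main.member_ids + sec.member_ids,
        member_rects=main.member_rects + sec.member_rects,
        top_fork=main.top_fork,
        end_fork=sec.end_fork,
        interior_forks=main.interior_forks + (fork,) + sec.interior_forks,
    )


def connect_at_fork(
    group: ForkGroup, angle_threshold: float = 100.0
) -> list[tuple[BranchSegmentModel, BranchSegmentModel, BranchSegmentModel]]:
    """Resolve one bifurcation: each main takes the secondary with the
    largest interior angle, provided it exceeds the threshold.

    Returns (main, secondary, merged) triples; a secondary is consumed
    by at most one main.
    """
    merges = []
    available = list(group.secondary_chains)
    for main in sorted(group.main_chains, key=lambda c: c.id):
        if not available:
            break
        scored = sorted(
            ((_bifurcation_angle(main, s, group.fork), -s.id, s) for s in available),
            reverse=True,
        )
        alpha, _, best = scored[0]
        if alpha > angle_threshold:
            merges.append((main, best, _merge_through_fork(main, best, group.fork)))
            available.remove(best)
    return merges


def connect_forks(
    chains: list[BranchSegmentModel], config: Config = Config()
) -> list[BranchSegmentModel]:
    """Apply :func:`connect_at_fork` over all forks to a fixpoint."""
    chains = list(chains)
    changed = True
    while changed:
        changed = False
        for group in fork_groups(chains):
            merges = connect_at_fork(group, config.bifurcation_angle_deg)
            if merges:
                consumed = {id(m) for triple in merges for m in triple[:2]}
                chains = [c for c in chains if id(c) not in consumed]
                chains.extend(t[2] for t in merges)
                changed = True
                break  # groups are stale after a merge; rebuild
    return chains


def _in_relaxed_sector(sector, p) -> bool:
    d = np.asarray(p, dtype=float) - sector.apex
    dist = float(np.linalg.norm(d))
    if dist == 0.0:
        return True
    if dist > sector.depth:
        return False
    return angle_between(d, sector.center_ray) <= sector.full_angle + 1e-7


def _free_link(
    lower: BranchSegmentModel, upper: BranchSegmentModel, config: Config
) -> Optional[float]:
    """Gap distance if ``upper``'s end terminal may join ``lower``'s top
    terminal under the relaxed search, else None.

    Membership uses the doubled opening (offset angle ≤ S instead of
    S/2) and reach 5·dis, checked from both chains.  The deflection
    constraint requires each chain's terminal axis direction to deviate
    from the joining line by at most its own half sector angle, which
    rejects parallel side-by-side chains.
    """
    if lower.top_fork is not None or upper.end_fork is not None:
        return None
    p_low = lower.V[0]
    p_up = upper.V[-1]
    sec_low = sector_for(lower, "top", config.free_depth_factor)
    sec_up = sector_for(upper, "end", config.free_depth_factor)
    if not _in_relaxed_sector(sec_low, p_up):
        return None
    if not _in_relaxed_sector(sec_up, p_low):
        return None
    join = p_up - p_low
    dist = float(np.linalg.norm(join))
    if dist > 0.0:
        alpha_low = angle_between(lower.V[0] - lower.V[1], join)
        alpha_up = angle_between(upper.V[-1] - upper.V[-2], -join)
        if alpha_low > sec_low.full_angle / 2.0 or alpha_up > sec_up.full_angle / 2.0:
            return None
    return dist


def _merge_free(upper: BranchSegmentModel, lower: BranchSegmentModel) -> BranchSegmentModel:
    return BranchSegmentModel(
        id=upper.id,
        V=np.vstack([upper.V, lower.V]),
        W_top=upper.W_top,
        W_end=lower.W_end,
        member_ids=upper.member_ids + lower.member_ids,
        member_rects=upper.member_rects + lower.member_rects,
        top_fork=upper.top_fork,
        end_fork=lower.end_fork,
        interior_forks=upper.interior_forks + lower.interior_forks,
    )


def connect_free(
    chains: list[BranchSegmentModel], config: Config = Config()
) -> list[BranchSegmentModel]:
    """Join fork-less chain pairs across gaps, nearest pair first,
    until no pair qualifies."""
    chains = list(chains)
    while True:
        best = None  # (dist, lower_id, upper_id, lower, upper)
        for lower in chains:
            for upper in chains:
                if lower is upper:
                    continue
                d = _free_link(lower, upper, config)
                if d is not None and (best is None or (d, lower.id, upper.id) < best[:3]):
                    best = (d, lower.id, upper.id, lower, upper)
        if best is None:
            return chains
        _, _, _, lower, upper = best
        chains = [c for c in chains if c is not lower and c is not upper]
        chains.append(_merge_free(upper, lower))


def prune_isolated(
    chains: list[BranchSegmentModel], enabled: bool = True
) -> list[BranchSegmentModel]:
    """Drop single-segment chains with no fork (leaf/petiole stand-ins)."""
    if not enabled:
        return list(chains)
    return [c for c in chains if c.n_members > 1 or c.forks]


def reconstruct_scene(
    instances: InstanceSet, config: Config = Config()
) -> list[BranchChain]:
    """Full pipeline: models → dedup → sector search → secondary
    connection → pruning → rendered chains."""
    if len(instances) == 0:
        return []
    segments, forks = build_models(instances)
    segments = dedup(segments, config.iou_dedup)
    models = reconstruct(segments, forks, config)
    if config.secondary_connection:
        models = connect_forks(models, config)
        models = connect_free(models, config)
    models = prune_isolated(models, config.prune_isolated)
    models = sorted(models, key=lambda m: min(m.member_ids))
    instance_masks = (
        {inst.id: inst.mask for inst in instances.instances}
        if config.render_mode == "masks"
        else None
    )
    out: list[BranchChain] = []
    for k, m in enumerate(models):
        chain = BranchChain(
            id=k,
            member_ids=m.member_ids,
            fork_ids=tuple(f.id for f in m.forks),
            axis=m.V,
            member_rects=m.member_rects,
            fork_rects=tuple(f.rect for f in m.forks),
            diameter_px=0.0,
        )
        chain = dc_replace(chain, diameter_px=chain_diameter(chain))
        mask = render_chain_mask(
            chain, instances.image_size, config.bridge_gaps, instance_masks
        )
        out.append(dc_replace(chain, mask=mask))
    return out
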