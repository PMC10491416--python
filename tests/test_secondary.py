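"""Secondary connection: fork joins, gap joins, pruning, full pipeline."""

import numpy as np
import pytest

from conftest import FORKED, SEGMENTED, make_scene, quad_rect
from vinebranch.config import Config
from vinebranch.secondary import (
    connect_at_fork,
    connect_forks,
    connect_free,
    fork_groups,
    prune_isolated,
    reconstruct_scene,
)
from vinebranch.segments import Fork, model_from_rect


def _seg(i, cx, cy, phi=0.0, length=20.0, width=6.0):
    return model_from_rect(i, quad_rect(cx, cy, length, width, phi))


def _with_fork(model, side, fork):
    return model.with_fork(side, fork)


class TestForkGroups:
    def test_main_and_secondary_roles(self):
        fork = Fork(id=9, rect=quad_rect(50, 50, 6, 6, 0.0))
        main = _with_fork(_seg(0, 50, 36), "end", fork)    # fork at its tail
        sec = _with_fork(_seg(1, 50, 64), "top", fork)     # fork at its head
        groups = fork_groups([main, sec])
        assert len(groups) == 1
        g = groups[0]
        assert g.fork is fork
        assert g.main_chains == (main,) and g.secondary_chains == (sec,)


class TestConnectAtFork:
    def _group(self, secondaries):
        fork = Fork(id=9, rect=quad_rect(50, 50, 6, 6, 0.0))
        main = _with_fork(_seg(0, 50, 36), "end", fork)
        secs = tuple(_with_fork(s, "top", fork) for s in secondaries)
        return fork_groups([main, *secs])[0]

    def test_straight_continuation_merged(self):
        g = self._group([_seg(1, 50, 64)])  # 180 deg through the fork
        merges = connect_at_fork(g, 100.0)
        assert len(merges) == 1
        merged = merges[0][2]
        assert merged.member_ids == (0, 1)
        assert merged.V.shape == (7, 2)  # 3 + fork center + 3
        assert np.allclose(merged.V[3], g.fork.center)
        # the joining fork is recorded as interior, both terminals open
        assert merged.top_fork is None and merged.end_fork is None
        assert g.fork in merged.interior_forks

    def test_perpendicular_limb_not_merged(self):
        g = self._group([_seg(1, 64, 50, phi=np.pi / 2)])  # ~90 deg
        assert connect_at_fork(g, 100.0) == []

    def test_argmax_picks_straightest(self):
        straight = _seg(1, 50, 64)
        slanted = _seg(2, 60, 62, phi=0.6)
        g = self._group([slanted, straight])
        merges = connect_at_fork(g, 100.0)
        assert len(merges) == 1
        assert merges[0][2].member_ids == (0, 1)

    def test_threshold_boundary(self):
        # limb at ~120 deg from the main axis: above 100 -> merged,
        # above a 130 threshold -> not
        limb = _seg(1, 50 + 14 * np.sin(1.05), 50 + 14 * np.cos(1.05), phi=1.05)
        g = self._group([limb])
        assert len(connect_at_fork(g, 100.0)) == 1
        assert connect_at_fork(g, 130.0) == []


class TestConnectForks:
    def test_chain_through_two_forks(self):
        f1 = Fork(id=10, rect=quad_rect(50, 50, 6, 6, 0.0))
        f2 = Fork(id=11, rect=quad_rect(50, 78, 6, 6, 0.0))
        top = _with_fork(_seg(0, 50, 36), "end", f1)
        mid = _with_fork(_with_fork(_seg(1, 50, 64), "top", f1), "end", f2)
        bot = _with_fork(_seg(2, 50, 92), "top", f2)
        out = connect_forks([top, mid, bot], Config())
        assert len(out) == 1
        assert out[0].member_ids == (0, 1, 2)


class TestConnectFree:
    def _column_pair(self, gap):
        # dis = 20 for both chains; relaxed reach = 5 * 20 = 100 from the
        # apex, i.e. the facing tip may be up to 100 - 10 away
        upper = _seg(0, 50, 30)
        lower = _seg(1, 50, 30 + 20 + gap)
        return upper, lower

    def test_collinear_gap_within_reach_merged(self):
        upper, lower = self._column_pair(gap=80.0)
        out = connect_free([upper, lower], Config())
        assert len(out) == 1
        assert out[0].member_ids == (0, 1)

    def test_gap_beyond_reach_not_merged(self):
        upper, lower = self._column_pair(gap=120.0)
        out = connect_free([upper, lower], Config())
        assert len(out) == 2

    def test_parallel_neighbors_rejected_by_deflection(self):
        # side-by-side chains: tips mutually inside the relaxed sectors'
        # reach, but the joining line is ~90 deg off both axes
        a = _seg(0, 50, 50)
        b = _seg(1, 65, 52)
        out = connect_free([a, b], Config())
        assert len(out) == 2

    def test_forked_terminals_excluded(self):
        upper, lower = self._column_pair(gap=40.0)
        fork = Fork(id=9, rect=quad_rect(200, 200, 6, 6, 0.0))
        upper = _with_fork(upper, "end", fork)
        out = connect_free([upper, lower], Config())
        assert len(out) == 2

    def test_nearest_pair_first(self):
        a = _seg(0, 50, 30)
        b = _seg(1, 50, 80)   # 30 px gap to a
        c = _seg(2, 50, 140)  # 40 px gap to b
        out = connect_free([a, b, c], Config())
        assert len(out) == 1
        assert out[0].member_ids == (0, 1, 2)


class TestPruneIsolated:
    def test_cases(self):
        single = _seg(0, 50, 30)
        pair = connect_free([_seg(1, 150, 30), _seg(2, 150, 60)], Config())[0]
        fork = Fork(id=9, rect=quad_rect(50, 58, 6, 6, 0.0))
        single_with_fork = _with_fork(_seg(3, 250, 30), "end", fork)
        out = prune_isolated([single, pair, single_with_fork])
        assert single not in out
        assert pair in out and single_with_fork in out

    def test_disabled(self):
        single = _seg(0, 50, 30)
        assert prune_isolated([single], enabled=False) == [single]


class TestReconstructScene:
    def _y_scene(self):
        """A vertical stem running through a fork plus a lateral limb."""
        shape = (220, 200)
        specs = [
            (0, SEGMENTED, 100, 30, 24, 7, 0.0),
            (1, SEGMENTED, 100, 56, 24, 7, 0.0),
            (2, FORKED, 100, 74, 8, 8, 0.0),
            (3, SEGMENTED, 100, 92, 24, 7, 0.0),
            (4, SEGMENTED, 100, 118, 24, 7, 0.0),
            # lateral limb leaving the fork at ~55 deg
            (5, SEGMENTED, 100 + 18, 74 + 13, 24, 6, 0.96),
            (6, SEGMENTED, 100 + 38, 74 + 27, 24, 6, 0.96),
        ]
        return make_scene(shape, specs)

    def test_y_scene_grouping(self):
        chains = reconstruct_scene(self._y_scene(), Config())
        members = sorted(tuple(c.member_ids) for c in chains)
        assert members == [(0, 1, 3, 4), (5, 6)]
        stem = next(c for c in chains if c.member_ids == (0, 1, 3, 4))
        assert stem.fork_ids == (2,)

    def test_masks_rendered_and_connected(self):
        chains = reconstruct_scene(self._y_scene(), Config())
        for c in chains:
            assert c.mask is not None and c.mask.any()
            assert c.mask.shape == (220, 200)

    def test_secondary_connection_toggle(self):
        on = reconstruct_scene(self._y_scene(), Config(secondary_connection=True))
        off = reconstruct_scene(self._y_scene(), Config(secondary_connection=False))
        assert len(off) >= len(on)  # fork splits remain without the pass

    def test_empty_scene(self):
        from vinebranch.masks_io import InstanceSet

        assert reconstruct_scene(InstanceSet((10, 10), ()), Config()) == []

    def test_deterministic(self):
        a = reconstruct_scene(self._y_scene(), Config())
        b = reconstruct_scene(self._y_scene(), Config())
        assert [c.member_ids for c in a] == [c.member_ids for c in b]
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.mask, cb.mask)
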