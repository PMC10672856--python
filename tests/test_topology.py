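"""Knot detection engine: KMT reduction, closures, Alexander invariants,
classification, and their invariance properties."""

import numpy as np
import pytest

import knotaudit as ka
from knotaudit.synthetic import _CURVES, _resample_closed
from knotaudit.topology import (
    KNOT_TABLE,
    PRIME_INVARIANTS,
    _odd_part,
    classify_loop,
    kmt_reduce,
)


class TestKMTReduce:
    def test_convex_planar_arc_collapses(self):
        t = np.linspace(0, np.pi, 50)
        arc = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        red = kmt_reduce(arc)
        assert len(red) <= 3
        np.testing.assert_allclose(red[0], arc[0])
        np.testing.assert_allclose(red[-1], arc[-1])

    def test_three_point_chain_unchanged(self):
        pts = np.array([[0.0, 0, 0], [1, 1, 0], [2, 0, 0]])
        np.testing.assert_allclose(kmt_reduce(pts), pts)

    def test_closed_trefoil_reduction_preserves_type(self, closed_trefoil):
        red = kmt_reduce(closed_trefoil, closed=True)
        assert len(red) < len(closed_trefoil)
        assert classify_loop(red, seed=1) == "3_1"
        assert classify_loop(closed_trefoil, seed=1) == "3_1"


class TestCloseChain:
    def test_straight_segment_closes_to_unknot(self):
        pts = np.column_stack(
            [np.arange(10) * 3.8, np.zeros(10), np.zeros(10)]
        )
        for method in ("direct", "random_sphere"):
            loops = ka.close_chain(pts, method=method, n_closures=5, seed=1)
            assert all(classify_loop(lp, seed=2) == "0_1" for lp in loops)

    def test_same_seed_identical_closures(self, trefoil_trace):
        a = ka.close_chain(trefoil_trace.coords, n_closures=4, seed=9)
        b = ka.close_chain(trefoil_trace.coords, n_closures=4, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_closure_point_is_far(self, trefoil_trace):
        pts = trefoil_trace.coords
        diag = np.linalg.norm(pts.max(axis=0) - pts.min(axis=0))
        loops = ka.close_chain(pts, n_closures=3, seed=0)
        for lp in loops:
            far = lp[-1]
            assert np.linalg.norm(far - pts.mean(axis=0)) >= 9 * diag

    def test_open_trefoil_consensus(self, trefoil_trace):
        lab = ka.classify_knot(
            trefoil_trace, n_closures=100, seed=5, early_stop=None
        )
        assert lab.notation == "3_1"
        assert lab.probability >= 0.9


class TestAlexander:
    def test_unknot_triangle(self):
        tri = np.array([[0.0, 0, 0], [4, 0, 0], [0, 4, 0]])
        assert ka.alexander_value(tri, t=-1, seed=0) == 1

    def test_closed_trefoil_determinant(self, closed_trefoil):
        assert ka.alexander_value(closed_trefoil, t=-1, seed=0) == 3
        assert ka.alexander_value(closed_trefoil, t=-2, seed=0) == 7

    @pytest.mark.parametrize(
        "name", ["3_1", "4_1", "5_1", "5_2", "6_1", "7_1"]
    )
    def test_published_invariant_pairs(self, name):
        """The geometric pipeline reproduces the published Alexander values
        |Delta(-1)| and odd part of |Delta(-2)| for every generated prime."""
        closed = _resample_closed(_CURVES[name], 400) * 10.0
        d1, d2 = PRIME_INVARIANTS[name]
        assert ka.alexander_value(closed, t=-1, seed=3) == d1
        assert ka.alexander_value(closed, t=-2, seed=3) == _odd_part(d2)

    def test_projection_independence(self, closed_trefoil):
        values = {
            ka.alexander_value(closed_trefoil, t=-2, seed=s)
            for s in range(6)
        }
        assert values == {7}


def test_invariant_table_is_collision_free():
    # the table build asserts uniqueness; spot-check the classic clash:
    # granny knot (9, 49) vs Stevedore 6_1 (9, 5) share |Delta(-1)| = 9
    assert KNOT_TABLE[(9, 49)] == "3_1#3_1"
    assert KNOT_TABLE[(9, 5)] == "6_1"
    assert KNOT_TABLE[(5, 11)] == "4_1"
    assert KNOT_TABLE[(5, 31)] == "5_1"


class TestClassifyProperties:
    def test_degenerate_chain_is_unknot(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        lab = ka.classify_knot(pts, n_closures=3, seed=1)
        assert lab == ka.KnotLabel("0_1", 1.0)

    def test_determinism_bit_for_bit(self, trefoil_trace):
        a = ka.classify_knot(trefoil_trace, n_closures=30, seed=4)
        b = ka.classify_knot(trefoil_trace, n_closures=30, seed=4)
        assert a == b

    def test_rigid_motion_invariance(self, trefoil_trace):
        rng = np.random.default_rng(0)
        base = ka.classify_knot(
            trefoil_trace, n_closures=50, seed=8, early_stop=None
        )
        for _ in range(5):
            m = rng.normal(size=(3, 3))
            q, r = np.linalg.qr(m)
            q *= np.sign(np.diag(r))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            moved = trefoil_trace.coords @ q.T + rng.normal(size=3) * 40
            lab = ka.classify_knot(
                moved, n_closures=50, seed=8, early_stop=None
            )
            assert lab.notation == base.notation
            assert abs(lab.probability - base.probability) <= 0.15

    def test_chain_reversal_invariance(self, trefoil_trace):
        fwd = ka.classify_knot(trefoil_trace, n_closures=40, seed=3)
        rev = ka.classify_knot(
            trefoil_trace.coords[::-1], n_closures=40, seed=3
        )
        assert fwd.notation == rev.notation

    def test_reduction_invariance(self, trefoil_trace):
        red = kmt_reduce(trefoil_trace.coords)
        a = ka.classify_knot(
            trefoil_trace, n_closures=40, seed=6, early_stop=None
        )
        b = ka.classify_knot(red, n_closures=40, seed=6, early_stop=None)
        assert a.notation == b.notation == "3_1"
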