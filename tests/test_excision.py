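"""Knot localization by excision: preconditions, determinant preservation,
and the minimal knotted core."""

import pytest

from bfacf.engine import AnnealingTriplet, generate_ensemble, run_annealing
from bfacf.excision import (
    ExcisionError,
    candidate_excisions,
    excise_once,
    minimal_knotted_core,
)
from bfacf.invariants import certify_knot
from bfacf.polygon import SphericalConfinement
from bfacf.seeds import KnotId, MINIMAL_TREFOIL_EDGES, minimal_embedding


BRICK = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0], [1, 1, 0], [0, 1, 0]]


@pytest.fixture()
def brick_1x2():
    """1x2 rectangle: vertices (1,0,0) and (1,1,0) are a distance-1 pair
    with arc distance 3, the smallest polygon admitting an excision."""
    from bfacf.polygon import LatticePolygon

    return LatticePolygon(BRICK)


class TestExciseOnce:
    def test_square_has_no_admissible_excision(self, square):
        assert candidate_excisions(square) == []
        with pytest.raises(ExcisionError):
            excise_once(square, 0, 1)  # chain neighbors: arc distance 1

    def test_convex_rectangle_has_no_candidates(self, rectangle_2x3):
        # on a convex 3x2 boundary all distance-1 pairs are chain neighbors
        assert candidate_excisions(rectangle_2x3) == []

    def test_brick_excision_shrinks(self, brick_1x2):
        pairs = candidate_excisions(brick_1x2)
        assert pairs == [(1, 4)]
        smaller = excise_once(brick_1x2, 1, 4, keep="shorter")
        assert smaller.validate().valid
        assert smaller.n == 4

    def test_keep_longer_removes_less(self, brick_1x2):
        short = excise_once(brick_1x2, 1, 4, keep="shorter")
        long_ = excise_once(brick_1x2, 1, 4, keep="longer")
        assert short.n <= long_.n
        assert short.n + long_.n == brick_1x2.n + 2  # arcs partition + 2 cut vertices

    def test_preconditions_raise_without_mutation(self, rectangle_2x3):
        before = rectangle_2x3.vertices.copy()
        with pytest.raises(ExcisionError, match="distance 1"):
            excise_once(rectangle_2x3, 0, 2)  # Euclidean distance 2
        with pytest.raises(ExcisionError):
            excise_once(rectangle_2x3, 0, 20)
        with pytest.raises(ExcisionError):
            excise_once(rectangle_2x3, 3, 3)
        assert (rectangle_2x3.vertices == before).all()


class TestMinimalKnottedCore:
    def test_minimal_trefoil_is_a_fixed_point(self):
        res = minimal_knotted_core(minimal_embedding("3_1"), KnotId("3_1"), n_restarts=2, seed=1)
        assert res.core_length == MINIMAL_TREFOIL_EDGES
        assert res.fraction == 1.0

    def test_unknot_excises_down_to_the_square(self, square):
        big = run_annealing(square, AnnealingTriplet(0.05, 0.3, 0.4), None, 40, 10_000_000, 4).polygon
        res = minimal_knotted_core(big, KnotId("0_1"), n_restarts=2, seed=2)
        assert res.core_length == 4
        assert res.fraction == pytest.approx(0.1)

    def test_globule_core_preserves_knot_and_respects_minimum(self):
        """On a trefoil globule the core keeps determinant 3, never dips
        below the lattice minimum, and the knot is delocalized (large
        core fraction)."""
        conf = SphericalConfinement(4.5)
        g = generate_ensemble(
            "3_1", AnnealingTriplet(0.10, 0.25, 0.25), conf, 300, 1,
            base_seed=5, randomize_steps=20_000,
        )[0]
        res = minimal_knotted_core(g.polygon, KnotId("3_1"), n_restarts=2, seed=3)
        assert res.core_length >= MINIMAL_TREFOIL_EDGES
        assert res.core_length < g.polygon.n
        assert certify_knot(res.core, KnotId("3_1")).passed
        assert 0 < res.fraction < 1

    def test_cross_restart_minimum_is_monotone(self):
        conf = SphericalConfinement(4.5)
        g = generate_ensemble(
            "3_1", AnnealingTriplet(0.10, 0.25, 0.25), conf, 200, 1,
            base_seed=8, randomize_steps=20_000,
        )[0]
        r1 = minimal_knotted_core(g.polygon, KnotId("3_1"), n_restarts=1, seed=4)
        r3 = minimal_knotted_core(g.polygon, KnotId("3_1"), n_restarts=3, seed=4)
        assert r3.core_length <= r1.core_length

    def test_wrong_expected_knot_is_rejected(self, square):
        with pytest.raises(ValueError, match="not certified"):
            minimal_knotted_core(square, KnotId("3_1"), n_restarts=1, seed=1)

    def test_deterministic_heuristic_reproduces(self, brick_1x2):
        a = minimal_knotted_core(brick_1x2, KnotId("0_1"), seed=1, deterministic=True)
        b = minimal_knotted_core(brick_1x2, KnotId("0_1"), seed=2, deterministic=True)
        assert a.core_length == b.core_length == 4
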