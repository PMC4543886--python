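"""BFACF move mechanics, equilibrium stationarity, and annealing growth."""

import numpy as np
import pytest

from bfacf.engine import (
    AnnealingError,
    AnnealingTriplet,
    FugacityParameter,
    apply_move,
    classify_move,
    derive_seed,
    generate_ensemble,
    propose_move,
    run_annealing,
    run_equilibrium,
    equilibrium_length_histogram,
    _perpendicular_directions,
)
from bfacf.invariants import polygon_determinant
from bfacf.polygon import BoxConfinement, SphericalConfinement

from _oracles import enumerate_box_polygons


def all_proposals(polygon):
    for i in range(polygon.n):
        step = polygon.vertices[(i + 1) % polygon.n] - polygon.vertices[i]
        for u in _perpendicular_directions(step):
            yield classify_move(polygon, i, u)


class TestMoveMechanics:
    def test_square_extrusion_is_feasible_plus2(self, square):
        p = classify_move(square, 0, (0, 0, 1))
        assert p.delta == 2 and p.feasible
        grown = apply_move(square, p)
        assert grown.n == 6 and grown.validate().valid

    def test_square_retraction_is_infeasible(self, square):
        # pushing an edge onto the opposite side proposes a -2 move, but the
        # square is minimal: the result would not be a polygon
        p = classify_move(square, 0, (0, 1, 0))
        assert p.delta == -2 and not p.feasible
        with pytest.raises(ValueError):
            apply_move(square, p)

    def test_hexagon_corner_flips(self, skew_hexagon):
        """The skew hexagon has 6 flippable corners, each proposable two
        ways, and 12 feasible extrusions (enumerated by hand)."""
        props = list(all_proposals(skew_hexagon))
        flips = [p for p in props if p.delta == 0 and p.feasible]
        grows = [p for p in props if p.delta == 2 and p.feasible]
        assert len(flips) == 12
        assert len(grows) == 12

    def test_zero_move_is_an_involution(self, skew_hexagon):
        p = next(p for p in all_proposals(skew_hexagon) if p.delta == 0 and p.feasible)
        once = apply_move(skew_hexagon, p)
        assert once.validate().valid and once.n == 6
        # flipping the same corner back restores the original vertex set
        back = [
            q for q in all_proposals(once)
            if q.delta == 0 and q.feasible
            and sorted(map(tuple, apply_move(once, q).vertices.tolist()))
            == sorted(map(tuple, skew_hexagon.vertices.tolist()))
        ]
        assert back

    def test_plus2_then_matching_minus2_restores(self, square):
        p = classify_move(square, 0, (0, 0, 1))
        grown = apply_move(square, p)
        # the inverse -2 proposal exists on the grown polygon
        inverses = [
            q for q in all_proposals(grown)
            if q.delta == -2 and q.feasible
            and sorted(map(tuple, apply_move(grown, q).vertices.tolist()))
            == sorted(map(tuple, square.vertices.tolist()))
        ]
        assert inverses

    def test_reversibility_on_random_small_polygons(self, square):
        """Every feasible proposal has a feasible inverse restoring the
        original polygon (checked along a short random walk)."""
        rng = np.random.default_rng(5)
        poly = square
        for _ in range(60):
            p = propose_move(poly, rng)
            if not p.feasible:
                continue
            new = apply_move(poly, p)
            assert new.validate().valid
            assert new.n == poly.n + p.delta
            target = sorted(map(tuple, poly.vertices.tolist()))
            inverse_exists = any(
                q.feasible
                and q.delta == -p.delta
                and sorted(map(tuple, apply_move(new, q).vertices.tolist())) == target
                for q in all_proposals(new)
            )
            assert inverse_exists
            if new.n <= 30:
                poly = new

    def test_confinement_blocks_growth(self, square):
        conf = SphericalConfinement(1.2, center=(0.5, 0.5, 0.0))
        p = classify_move(square, 0, (0, 0, 1), confinement=conf)
        assert p.delta == 2 and not p.feasible


class TestEquilibrium:
    def test_zero_steps_is_identity(self, square):
        assert run_equilibrium(square, 0.1, 0, 1) == square

    def test_fugacity_range_is_validated(self):
        with pytest.raises(ValueError):
            FugacityParameter(0.5)
        with pytest.raises(ValueError):
            FugacityParameter(-0.1)

    def test_same_seed_reproduces_and_seeds_differ(self, square):
        a = run_equilibrium(square, 0.1, 100_000, 42)
        b = run_equilibrium(square, 0.1, 100_000, 42)
        c = run_equilibrium(square, 0.1, 100_000, 43)
        assert a == b
        assert a != c
        # both are valid unknots
        for poly in (a, c):
            assert poly.validate().valid
            assert polygon_determinant(poly) == 1

    def test_knot_class_is_conserved_along_trajectory(self):
        from bfacf.seeds import minimal_embedding

        poly = minimal_embedding("3_1")
        for k in range(5):  # checkpoints along one trajectory
            poly = run_equilibrium(poly, 0.1, 30_000, derive_seed(7, k))
            assert polygon_determinant(poly) == 3

    def test_stationary_distribution_matches_exact_enumeration(self, square):
        """In a (2,3,3) box the empirical length-class frequencies converge
        to P(n) ~ C(n) z^n, with C(n) from brute-force enumeration; compared
        within 3 cross-chain standard errors."""
        z = 0.2
        box = BoxConfinement((0, 0, 0), (1, 2, 2))
        counts = enumerate_box_polygons((2, 3, 3))
        weights = {n: c * z**n for n, c in counts.items()}
        total = sum(weights.values())
        theory = {n: w / total for n, w in weights.items()}

        n_chains = 12
        freqs = []
        for c in range(n_chains):
            hist = equilibrium_length_histogram(
                square, z, 800_000, derive_seed(100, c), confinement=box, sample_every=50
            )
            tot = hist.sum()
            freqs.append({n: hist[n] / tot for n in counts})
        for n in (4, 6, 8):
            vals = np.array([f[n] for f in freqs])
            mean = vals.mean()
            se = vals.std(ddof=1) / np.sqrt(n_chains)
            assert abs(mean - theory[n]) < 3 * se + 1e-4, (n, mean, theory[n], se)


class TestAnnealing:
    def test_triplet_validation(self):
        with pytest.raises(ValueError):
            AnnealingTriplet(0.5, 0.5, 0.2)
        with pytest.raises(ValueError):
            AnnealingTriplet(-0.1, 0.2, 0.2)
        assert AnnealingTriplet(0.1, 0.25, 0.25).p_stay == pytest.approx(0.4)

    def test_pure_growth_reaches_target_quickly(self, square):
        g = run_annealing(square, AnnealingTriplet(0, 0, 1), None, 6, 10_000, 1)
        assert g.polygon.n == 6

    def test_budget_exhaustion_reports_length(self, square):
        with pytest.raises(AnnealingError) as err:
            run_annealing(square, AnnealingTriplet(0, 0, 0.01), None, 400, 500, 2)
        assert 4 <= err.value.length_reached < 400

    def test_completion_rate_monotone_in_budget(self, square):
        conf = SphericalConfinement(4.5)
        done = {budget: 0 for budget in (1_500, 300_000)}
        for budget in done:
            for k in range(10):
                try:
                    run_annealing(square, AnnealingTriplet(0.1, 0.25, 0.25), conf, 300, budget, derive_seed(3, k))
                    done[budget] += 1
                except AnnealingError:
                    pass
        assert done[300_000] == 10
        assert done[300_000] >= done[1_500]

    def test_slow_triplet_needs_more_proposals(self):
        """Raising p(-2) at fixed p(0), p(+2) slows sphere filling."""
        from bfacf.seeds import minimal_embedding

        conf = SphericalConfinement(4.5)
        tre = minimal_embedding("3_1")
        totals = {}
        for trip in [(0.10, 0.25, 0.25), (0.40, 0.25, 0.25)]:
            props = []
            for k in range(20):
                g = run_annealing(tre, AnnealingTriplet(*trip), conf, 300, 50_000_000, derive_seed(11, k))
                props.append(g.n_proposals)
            totals[trip] = np.mean(props)
        assert totals[(0.40, 0.25, 0.25)] > totals[(0.10, 0.25, 0.25)]

    def test_globule_confined_and_knot_preserved(self):
        conf = SphericalConfinement(4.5)
        globs = generate_ensemble(
            "3_1", AnnealingTriplet(0.10, 0.25, 0.25), conf, 300, 3,
            base_seed=77, randomize_steps=20_000,
        )
        for g in globs:
            assert g.polygon.n == 300
            assert np.all(conf.contains(g.polygon.vertices))
            assert polygon_determinant(g.polygon) == 3
            assert 0 < g.fill_fraction < 1

    def test_ensemble_reproducibility(self):
        conf = SphericalConfinement(4.5)
        kw = dict(confinement=conf, target_length=200, n_conformations=2, randomize_steps=10_000)

        def run(seed):
            return generate_ensemble("0_1", AnnealingTriplet(0.10, 0.25, 0.25), kw["confinement"],
                                     kw["target_length"], kw["n_conformations"], base_seed=seed,
                                     randomize_steps=kw["randomize_steps"])

        a, b, c = run(5), run(5), run(6)
        assert all(x.polygon == y.polygon for x, y in zip(a, b))
        assert any(x.polygon != y.polygon for x, y in zip(a, c))
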