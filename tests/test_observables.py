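"""Contact-probability and end-to-end curves versus brute-force oracles,
plus the log-log slope fitter."""

import math

import numpy as np
import pytest

from bfacf.engine import AnnealingTriplet, derive_seed, run_annealing
from bfacf.observables import (
    ContactCurve,
    DEFAULT_DIAGONAL_WEIGHT,
    bootstrap_slope,
    contact_curve,
    end_to_end_curve,
    ensemble_average,
    fit_loglog_slope,
)
from bfacf.polygon import LatticePolygon

from _oracles import naive_pair_curves


def random_polygons(n_target, count, seed=0):
    """Valid polygons of roughly n_target edges grown from the square."""
    square = LatticePolygon([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
    out = []
    for k in range(count):
        g = run_annealing(
            square, AnnealingTriplet(0.1, 0.3, 0.4), None, n_target, 50_000_000, derive_seed(seed, k)
        )
        out.append(g.polygon)
    return out


class TestCurves:
    def test_square_hand_values(self, square):
        c = contact_curve(square)
        # the two diagonals at arc distance 2 and Euclidean sqrt(2)
        assert c.P[1] == pytest.approx(2 * DEFAULT_DIAGONAL_WEIGHT / 4)
        assert c.P[1] == pytest.approx(math.sqrt(2) / 4)
        assert c.R[0] == pytest.approx(1.0)  # R(1) = 1 on a unit-step lattice
        assert c.R[1] == pytest.approx(math.sqrt(2))

    def test_rectangle_against_naive_oracle(self, rectangle_2x3):
        c = contact_curve(rectangle_2x3)
        P, R = naive_pair_curves(rectangle_2x3.vertices, DEFAULT_DIAGONAL_WEIGHT)
        np.testing.assert_allclose(c.P, P, atol=1e-12)
        np.testing.assert_allclose(c.R, R, atol=1e-12)

    def test_random_polygons_match_naive_oracle(self):
        for poly in random_polygons(100, 3, seed=2):
            c = contact_curve(poly)
            P, R = naive_pair_curves(poly.vertices, DEFAULT_DIAGONAL_WEIGHT)
            np.testing.assert_allclose(c.P, P, atol=1e-12)
            np.testing.assert_allclose(c.R, R, atol=1e-12)
            assert np.all(c.R <= c.s + 1e-12)  # R(s) <= s
            assert c.R[0] == pytest.approx(1.0)

    def test_end_to_end_alias(self, square):
        assert np.allclose(end_to_end_curve(square).R, contact_curve(square).R)

    def test_invariance_under_relabeling_and_reversal(self):
        poly = random_polygons(60, 1, seed=4)[0]
        c0 = contact_curve(poly)
        rolled = LatticePolygon(np.roll(poly.vertices, 7, axis=0), check=False)
        reversed_ = LatticePolygon(poly.vertices[::-1].copy(), check=False)
        np.testing.assert_allclose(contact_curve(rolled).P, c0.P, atol=1e-12)
        np.testing.assert_allclose(contact_curve(reversed_).P, c0.P, atol=1e-12)


class TestEnsembleAverage:
    def test_average_identities(self, square):
        c = contact_curve(square)
        one = ensemble_average([c])
        np.testing.assert_allclose(one.P, c.P)
        both = ensemble_average([c, c])
        np.testing.assert_allclose(both.P, c.P)
        assert both.n_conformations == 2

    def test_average_matches_manual_mean(self):
        curves = [contact_curve(p) for p in random_polygons(80, 4, seed=6)]
        avg = ensemble_average(curves)
        np.testing.assert_allclose(avg.P, np.mean([c.P for c in curves], axis=0))
        np.testing.assert_allclose(avg.R, np.mean([c.R for c in curves], axis=0))

    def test_mixed_lengths_rejected(self, square):
        big = random_polygons(60, 1, seed=8)[0]
        with pytest.raises(ValueError, match="mixed"):
            ensemble_average([contact_curve(square), contact_curve(big)])


def synthetic_curve(fn, n=200):
    s = np.arange(1, n + 1)
    vals = fn(s)
    return ContactCurve(s=s, P=vals, R=vals, n_pairs=np.full(n, 10), n=2 * n)


class TestSlopeFit:
    @pytest.mark.parametrize(
        "fn, expected",
        [
            (lambda s: 1.0 / s, -1.0),
            (lambda s: 7.0 * s**-1.5, -1.5),
            (lambda s: s**0.27, 0.27),
        ],
    )
    def test_exact_power_laws(self, fn, expected):
        fit = fit_loglog_slope(synthetic_curve(fn), 9, 55, "P")
        assert fit.slope == pytest.approx(expected, abs=1e-12)
        assert fit.stderr == pytest.approx(0.0, abs=1e-10)
        assert fit.ci95[0] <= fit.slope <= fit.ci95[1]
        assert fit.n_points == 47

    def test_scale_invariance(self):
        c1 = synthetic_curve(lambda s: s**-1.2)
        c2 = synthetic_curve(lambda s: 37.0 * s**-1.2)
        f1 = fit_loglog_slope(c1, 9, 55)
        f2 = fit_loglog_slope(c2, 9, 55)
        assert f1.slope == pytest.approx(f2.slope, abs=1e-12)

    def test_rejects_bad_ranges(self):
        c = synthetic_curve(lambda s: 1.0 / s)
        with pytest.raises(ValueError):
            fit_loglog_slope(c, 55, 9)
        with pytest.raises(ValueError, match="nonpositive"):
            fit_loglog_slope(synthetic_curve(lambda s: 1.0 / s - 0.05), 9, 55)
        with pytest.raises(ValueError, match="3 points"):
            fit_loglog_slope(synthetic_curve(lambda s: 1.0 / s), 9, 10)

    def test_bootstrap_se_reasonable(self):
        rng = np.random.default_rng(3)
        curves = []
        s = np.arange(1, 101)
        for _ in range(20):
            noise = np.exp(rng.normal(0, 0.1, size=s.size))
            vals = s**-1.1 * noise
            curves.append(ContactCurve(s=s, P=vals, R=vals, n_pairs=np.full(s.size, 1), n=200))
        mean, se = bootstrap_slope(curves, "P", 9, 55, n_boot=300, seed=1)
        assert se > 0
        assert mean == pytest.approx(-1.1, abs=0.1)


def test_diagonal_weight_robustness(unknot_reference_ensemble):
    """Doubling the diagonal-contact weight changes P(s) pointwise but moves
    the fitted ensemble slope by less than the bootstrap SE."""
    curves, globs = unknot_reference_ensemble
    polys = [g.polygon for g in globs][:24]
    c_default = [contact_curve(p, DEFAULT_DIAGONAL_WEIGHT) for p in polys]
    c_double = [contact_curve(p, 2 * DEFAULT_DIAGONAL_WEIGHT) for p in polys]
    assert not np.allclose(ensemble_average(c_default).P, ensemble_average(c_double).P)
    f1 = fit_loglog_slope(ensemble_average(c_default), 9, 55)
    f2 = fit_loglog_slope(ensemble_average(c_double), 9, 55)
    _, bse = bootstrap_slope(c_default, "P", 9, 55, n_boot=300, seed=9)
    assert abs(f1.slope - f2.slope) < bse
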