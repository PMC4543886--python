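"""Shared fixtures: small reference polygons and the ensembles used by the
acceptance tests (session-scoped so several tests can share one ensemble)."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from bfacf.engine import AnnealingTriplet, generate_ensemble
from bfacf.observables import contact_curve
from bfacf.polygon import LatticePolygon, SphericalConfinement

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# ---------------------------------------------------------------------------
# study-scale constants: the reference protocol is 4000-edge globules in a
# radius-10.5 sphere; replicate counts are desk-scale (see docs/methods.md)
# ---------------------------------------------------------------------------
RADIUS = 10.5
TARGET_LENGTH = 4000
N_PRIMARY = 56  # replicates for unknot / trefoil / p0-regime ensembles
N_COMPOSITE = 20  # replicates per (3_1)^n ensemble
RANDOMIZE_STEPS = 100_000
BASE_SEED = 20150821


@pytest.fixture()
def square() -> LatticePolygon:
    return LatticePolygon([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])


@pytest.fixture()
def skew_hexagon() -> LatticePolygon:
    """Non-planar 6-edge polygon; has 6 flippable corners (12 proposals)."""
    return LatticePolygon(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1], [0, 1, 1], [0, 0, 1]]
    )


@pytest.fixture()
def rectangle_2x3() -> LatticePolygon:
    return LatticePolygon(
        [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [3, 1, 0],
         [3, 2, 0], [2, 2, 0], [1, 2, 0], [0, 2, 0], [0, 1, 0]]
    )


def _ensemble_curves(knot: str, triplet, n_conf: int, seed_offset: int):
    conf = SphericalConfinement(RADIUS)
    globs = generate_ensemble(
        knot,
        AnnealingTriplet(*triplet),
        conf,
        TARGET_LENGTH,
        n_conf,
        base_seed=BASE_SEED + seed_offset,
        randomize_steps=RANDOMIZE_STEPS,
    )
    return [contact_curve(g.polygon) for g in globs], globs


@pytest.fixture(scope="session")
def unknot_reference_ensemble():
    """Unknot globules at the reference triplet (0.10, 0.25, 0.25)."""
    return _ensemble_curves("0_1", (0.10, 0.25, 0.25), N_PRIMARY, 1)


@pytest.fixture(scope="session")
def trefoil_reference_ensemble():
    return _ensemble_curves("3_1", (0.10, 0.25, 0.25), N_PRIMARY, 2)


@pytest.fixture(scope="session")
def unknot_p040_ensemble():
    """Unknot globules at the p(0) = 0.40 regime triplet (0.25, 0.40, 0.25)."""
    return _ensemble_curves("0_1", (0.25, 0.40, 0.25), N_PRIMARY, 3)


@pytest.fixture(scope="session")
def composite_ensembles():
    """(3_1)^n ensembles for n = 20, 40, 100 at the reference triplet."""
    out = {}
    for i, n in enumerate((20, 40, 100)):
        curves, _ = _ensemble_curves(f"3_1x{n}", (0.10, 0.25, 0.25), N_COMPOSITE, 10 + i)
        out[n] = curves
    return out
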