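"""Lattice polygon invariants, arc distances and the conformation format."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bfacf.polygon import (
    BoxConfinement,
    ConformationFormatError,
    LatticePolygon,
    SphericalConfinement,
    arc_distance,
    read_conformations,
    validate_polygon,
    write_conformations,
    write_xyz,
)


@pytest.mark.parametrize(
    "vertices, valid, reason_part",
    [
        ([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], True, None),
        ([[0, 0, 0], [2, 0, 0], [2, 1, 0], [0, 1, 0]], False, "non-unit step"),
        ([[0, 0, 0], [1, 0, 0], [0, 0, 0], [-1, 0, 0]], False, "repeated vertex"),
        ([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 2, 0], [0, 2, 0], [0, 1, 0], [0, 1, 1]], False, "even"),
        ([[0, 0, 0], [1, 0, 0]], False, "at least 4"),
        ([[0.5, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], False, "non-integer"),
    ],
)
def test_validate_polygon_reports_first_violation(vertices, valid, reason_part):
    report = validate_polygon(np.array(vertices))
    assert report.valid is valid
    if reason_part:
        assert reason_part in report.reason


def test_non_unit_step_reports_offending_index():
    report = validate_polygon(np.array([[0, 0, 0], [2, 0, 0], [2, 1, 0], [0, 1, 0]]))
    assert report.index == 0


def test_invalid_polygon_constructor_raises(square):
    with pytest.raises(ValueError, match="repeated vertex"):
        LatticePolygon([[0, 0, 0], [1, 0, 0], [0, 0, 0], [-1, 0, 0]])
    assert square.n == 4 == len(square)


@pytest.mark.parametrize("i, j, expected", [(0, 10, 10), (0, 95, 5), (7, 7, 0)])
def test_arc_distance_cyclic_convention(i, j, expected):
    # a 100-edge ring: 50 steps out along x, 50 back shifted in y
    out = [[k, 0, 0] for k in range(50)]
    back = [[49, 1, 0]] + [[k, 1, 0] for k in range(48, -1, -1)]
    poly = LatticePolygon(out + back)
    assert poly.n == 100
    assert arc_distance(poly, i, j) == expected


@given(st.integers(0, 99), st.integers(0, 99))
def test_arc_distance_symmetric_and_bounded(i, j):
    out = [[k, 0, 0] for k in range(50)]
    back = [[49, 1, 0]] + [[k, 1, 0] for k in range(48, -1, -1)]
    poly = LatticePolygon(out + back)
    d = arc_distance(poly, i, j)
    assert d == arc_distance(poly, j, i)
    assert 0 <= d <= poly.n // 2


def test_arc_distance_rejects_out_of_range(square):
    with pytest.raises(IndexError):
        arc_distance(square, 0, 4)


def test_conformation_roundtrip_is_bit_identical(tmp_path, square, skew_hexagon):
    path = tmp_path / "confs.txt"
    write_conformations([square, skew_hexagon], path, comments=["knot=0_1 seed=1"])
    back = read_conformations(path)
    assert len(back) == 2
    assert back[0] == square and back[1] == skew_hexagon
    # a second write of the parsed objects reproduces the payload lines
    path2 = tmp_path / "confs2.txt"
    write_conformations(back, path2)
    payload = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert payload == path2.read_text().splitlines()


def test_malformed_conformation_file_names_line(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("0 0 0\n1 0 0\n1 a 0\n0 1 0\n")
    with pytest.raises(ConformationFormatError, match="line 3"):
        read_conformations(path)
    path.write_text("0 0 0\n1 0 0\n")
    with pytest.raises(ConformationFormatError):
        read_conformations(path)


def test_xyz_export(tmp_path, square):
    path = tmp_path / "c.xyz"
    write_xyz(square, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "4"
    assert lines[2].startswith("C ")


def test_spherical_confinement_counts_small_radius_sites():
    # radius 1.5 about a lattice point: the site itself, 6 nearest
    # neighbors, and 12 sqrt(2) diagonals
    conf = SphericalConfinement(1.5)
    assert conf.lattice_site_count() == 19
    assert bool(conf.contains(np.array([[1, 1, 0]]))[0])
    assert not bool(conf.contains(np.array([[1, 1, 1]]))[0])


def test_box_confinement_contains_and_count():
    box = BoxConfinement((0, 0, 0), (1, 2, 2))
    assert box.lattice_site_count() == 18
    assert bool(box.contains(np.array([1, 2, 2])))
    assert not bool(box.contains(np.array([2, 0, 0])))
    with pytest.raises(ValueError):
        BoxConfinement((0, 0, 0), (-1, 2, 2))
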