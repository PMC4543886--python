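"""Self-avoiding lattice polygons on the simple cubic lattice Z^3.

A lattice polygon is a closed, self-avoiding, unit-step walk: consecutive
vertices (cyclically) differ by exactly one unit step along a coordinate
axis, no vertex is visited twice, and the number of edges equals the number
of vertices.  Closed polygons on Z^3 always have even length and at least
4 edges.  This module holds the central state object (:class:`LatticePolygon`),
spherical confinement, cyclic arc distances, and the plain-text conformation
file format used by every other module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LatticePolygon",
    "SphericalConfinement",
    "BoxConfinement",
    "ValidationReport",
    "validate_polygon",
    "arc_distance",
    "read_conformations",
    "write_conformations",
    "write_xyz",
]

# The three lattice axes; a legal step is +-e_k for k in {0,1,2}.
_UNIT_STEPS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of :func:`validate_polygon`.

    ``valid`` is True iff all polygon invariants hold; otherwise ``reason``
    names the first violated invariant and ``index`` the offending vertex
    (or edge start) index.
    """

    valid: bool
    reason: str | None = None
    index: int | None = None

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.valid


def validate_polygon(vertices: Sequence[Sequence[int]] | np.ndarray) -> ValidationReport:
    """Check the closed self-avoiding polygon invariants.

    Invariants: integer coordinates; every cyclically consecutive pair of
    vertices differs by one unit step; all vertices distinct; even length
    >= 4.  Invalid input yields an invalid report, never an exception.
    """
    v = np.asarray(vertices)
    if v.ndim != 2 or v.shape[0] == 0 or v.shape[1] != 3:
        return ValidationReport(False, "vertices must be a non-empty (n, 3) array", None)
    if not np.issubdtype(v.dtype, np.integer):
        if not np.all(v == np.round(v)):
            return ValidationReport(False, "non-integer coordinate", None)
        v = v.astype(np.int64)
    n = v.shape[0]
    if n < 4:
        return ValidationReport(False, f"polygon needs at least 4 vertices, got {n}", None)
    if n % 2 != 0:
        return ValidationReport(False, f"closed lattice polygons have even length, got {n}", None)
    steps = np.roll(v, -1, axis=0) - v
    step_ok = np.sum(np.abs(steps), axis=1) == 1
    if not np.all(step_ok):
        i = int(np.argmin(step_ok))
        return ValidationReport(False, "non-unit step", i)
    seen: dict[tuple[int, int, int], int] = {}
    for i, row in enumerate(map(tuple, v.tolist())):
        if row in seen:
            return ValidationReport(False, f"repeated vertex (first at index {seen[row]})", i)
        seen[row] = i
    return ValidationReport(True)


class LatticePolygon:
    """A closed self-avoiding unit-step polygon on Z^3.

    Parameters
    ----------
    vertices
        Ordered (n, 3) integer array (or nested sequence) of lattice
        vertices.  The closing edge from the last vertex back to the first
        is implicit.
    check
        Validate the polygon invariants on construction (default).  Internal
        callers that construct provably valid polygons may pass False.
    """

    __slots__ = ("vertices",)

    def __init__(self, vertices: Sequence[Sequence[int]] | np.ndarray, check: bool = True):
        v = np.ascontiguousarray(np.asarray(vertices, dtype=np.int64))
        if check:
            report = validate_polygon(v)
            if not report.valid:
                raise ValueError(
                    f"invalid lattice polygon: {report.reason}"
                    + (f" at index {report.index}" if report.index is not None else "")
                )
        self.vertices = v
        self.vertices.setflags(write=False)

    @property
    def n(self) -> int:
        """Edge count (= vertex count for a closed polygon)."""
        return int(self.vertices.shape[0])

    def __len__(self) -> int:
        return self.n

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LatticePolygon):
            return NotImplemented
        return self.vertices.shape == other.vertices.shape and bool(
            np.all(self.vertices == other.vertices)
        )

    def __hash__(self) -> int:
        return hash(self.vertices.tobytes())

    def __repr__(self) -> str:
        return f"LatticePolygon(n={self.n})"

    def translated(self, offset: Sequence[int]) -> "LatticePolygon":
        """Return a copy translated by an integer lattice vector."""
        off = np.asarray(offset, dtype=np.int64)
        return LatticePolygon(self.vertices + off, check=False)

    def transformed(self, matrix: Sequence[Sequence[int]]) -> "LatticePolygon":
        """Apply an integer lattice symmetry (signed permutation matrix)."""
        m = np.asarray(matrix, dtype=np.int64)
        return LatticePolygon(self.vertices @ m.T, check=True)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def max_radius(self, center: Sequence[float] = (0.0, 0.0, 0.0)) -> float:
        """Largest Euclidean distance of any vertex from ``center``."""
        d = self.vertices - np.asarray(center, dtype=float)
        return float(np.sqrt((d * d).sum(axis=1).max()))

    def validate(self) -> ValidationReport:
        return validate_polygon(self.vertices)


@dataclass(frozen=True)
class SphericalConfinement:
    """A confining sphere; a vertex v is admissible iff |v - center| <= radius."""

    radius: float
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("confinement radius must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized admissibility test for an (n, 3) array of points."""
        d = np.asarray(points, dtype=float) - np.asarray(self.center, dtype=float)
        return (d * d).sum(axis=-1) <= self.radius**2 + 1e-12

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer lower/upper corners of a box containing all admissible sites."""
        c = np.asarray(self.center, dtype=float)
        lo = np.floor(c - self.radius).astype(np.int64)
        hi = np.ceil(c + self.radius).astype(np.int64)
        return lo, hi

    def lattice_site_count(self) -> int:
        """Number of admissible Z^3 lattice sites (the sphere's capacity)."""
        r = int(math.floor(self.radius)) + 1
        cx, cy, cz = self.center
        axes = [np.arange(math.floor(c) - r, math.ceil(c) + r + 1) for c in self.center]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        d2 = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2
        return int(np.count_nonzero(d2 <= self.radius**2 + 1e-12))


@dataclass(frozen=True)
class BoxConfinement:
    """An axis-aligned box of admissible lattice sites, ``lo <= v <= hi``.

    Mostly used for exact-enumeration tests, where every polygon fitting the
    box can be counted by brute force.
    """

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(h < l for l, h in zip(self.lo, self.hi)):
            raise ValueError("box upper corner must dominate the lower corner")

    @property
    def center(self) -> tuple[float, float, float]:
        return tuple((l + h) / 2.0 for l, h in zip(self.lo, self.hi))

    @property
    def radius(self) -> float:  # half the space diagonal; used only for sizing
        return 0.5 * math.dist(self.lo, self.hi)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points)
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((p >= lo) & (p <= hi), axis=-1)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.lo, dtype=np.int64), np.asarray(self.hi, dtype=np.int64)

    def lattice_site_count(self) -> int:
        return int(np.prod([h - l + 1 for l, h in zip(self.lo, self.hi)]))


def arc_distance(polygon: LatticePolygon, i: int, j: int) -> int:
    """Cyclic arc (genomic) distance between vertex indices ``i`` and ``j``.

    Defined as the shorter of the two arcs around the closed polygon,
    ``min(|i-j|, n-|i-j|)``; symmetric and bounded by ``n/2``.
    """
    n = polygon.n
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"vertex indices ({i}, {j}) out of range for n={n}")
    d = abs(i - j)
    return min(d, n - d)


# ---------------------------------------------------------------------------
# Conformation file format: one vertex per line as "x y z"; conformations
# separated by a single blank line; '#' lines are comments/metadata.
# ---------------------------------------------------------------------------


class ConformationFormatError(ValueError):
    """Raised for malformed conformation files; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def read_conformations(path: str | Path, check: bool = True) -> list[LatticePolygon]:
    """Read all conformations from a plain-text conformation file."""
    polygons: list[LatticePolygon] = []
    block: list[list[int]] = []
    block_start = 1

    def flush(end_line: int) -> None:
        nonlocal block
        if not block:
            return
        if check:
            report = validate_polygon(np.array(block, dtype=np.int64))
            if not report.valid:
                where = block_start + (report.index or 0)
                raise ConformationFormatError(f"invalid polygon: {report.reason}", where)
        polygons.append(LatticePolygon(np.array(block, dtype=np.int64), check=False))
        block = []

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                continue
            if not line:
                flush(lineno)
                block_start = lineno + 1
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ConformationFormatError(
                    f"expected 3 whitespace-separated integers, got {len(parts)} fields", lineno
                )
            try:
                coords = [int(p) for p in parts]
            except ValueError:
                raise ConformationFormatError(f"non-integer coordinate in {line!r}", lineno) from None
            if not block:
                block_start = lineno
            block.append(coords)
        flush(lineno if "lineno" in locals() else 1)
    return polygons


def write_conformations(
    polygons: Iterable[LatticePolygon],
    path: str | Path,
    comments: Sequence[str] | None = None,
) -> None:
    """Write conformations to ``path`` in the canonical plain-text format.

    ``comments`` (optional) are written as leading ``#`` metadata lines.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for c in comments or ():
            fh.write(f"# {c}\n")
        first = True
        for poly in polygons:
            if not first:
                fh.write("\n")
            first = False
            for x, y, z in poly.vertices.tolist():
                fh.write(f"{x} {y} {z}\n")


def write_xyz(polygon: LatticePolygon, path: str | Path, element: str = "C") -> None:
    """Export one conformation in XYZ format for visualization."""
    v = polygon.vertices
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(v)}\n")
        fh.write("lattice polygon\n")
        for x, y, z in v.tolist():
            fh.write(f"{element} {x} {y} {z}\n")
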