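"""Knot localization by arc excision.

To measure how much of a knotted globule the knot actually occupies, the
polygon is cut at a pair of vertices at Euclidean distance 1 and as much of
the conformation as possible is excised while retaining the original knot
type: one of the two arcs between the cut points is replaced by the single
unit edge joining them, and the excision is kept only if the resulting
polygon is still self-avoiding and its certified Alexander determinant is
unchanged.  Repeating this from many random cut pairs (with restarts)
shrinks the polygon onto a *minimal knotted core*; its length, as a
fraction of the original length, quantifies how delocalized the knot is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .polygon import LatticePolygon, validate_polygon
from .invariants import certify_knot
from .engine import derive_seed

__all__ = ["ExcisionError", "excise_once", "candidate_excisions", "minimal_knotted_core", "CoreResult"]


class ExcisionError(ValueError):
    """Raised when an excision precondition fails; the polygon is unchanged."""


def candidate_excisions(polygon: LatticePolygon, min_arc: int = 3) -> list[tuple[int, int]]:
    """All vertex index pairs (i, j) at Euclidean distance 1 and arc distance >= min_arc."""
    v = polygon.vertices
    n = polygon.n
    # pairs at distance 1 via a position hash
    index = {tuple(p): i for i, p in enumerate(v.tolist())}
    out = []
    steps = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
    for i, p in enumerate(v.tolist()):
        for s in steps:
            q = (p[0] + s[0], p[1] + s[1], p[2] + s[2])
            j = index.get(q)
            if j is None or j <= i:
                continue
            d = abs(i - j)
            arc = min(d, n - d)
            if arc >= min_arc:
                out.append((i, j))
    return out


def excise_once(polygon: LatticePolygon, i: int, j: int, keep: str = "shorter") -> LatticePolygon:
    """Replace one arc between vertices i and j with the direct unit edge.

    ``keep`` selects which arc survives: ``'shorter'`` (default, removing as
    much material as possible) or ``'longer'``.  Raises
    :class:`ExcisionError` if i and j are not at Euclidean distance 1, the
    arc distance is < 3, or the closed-up polygon would not be
    self-avoiding; the input polygon is never modified.
    """
    v = polygon.vertices
    n = polygon.n
    if not (0 <= i < n and 0 <= j < n):
        raise ExcisionError(f"vertex indices ({i}, {j}) out of range")
    if i == j:
        raise ExcisionError("need two distinct vertices")
    d2 = int(((v[i] - v[j]) ** 2).sum())
    if d2 != 1:
        raise ExcisionError(f"vertices not at Euclidean distance 1 (d^2={d2})")
    if i > j:
        i, j = j, i
    inner = j - i  # arc through increasing indices
    outer = n - inner
    if min(inner, outer) < 3:
        raise ExcisionError("arc distance < 3; nothing to excise")
    arc_a = v[i : j + 1]  # inner arc, i..j
    arc_b = np.concatenate([v[j:], v[: i + 1]])  # outer arc, j..i (wrapping)
    if keep == "shorter":
        kept = arc_a if inner <= outer else arc_b
    elif keep == "longer":
        kept = arc_a if inner > outer else arc_b
    else:
        raise ValueError("keep must be 'shorter' or 'longer'")
    # kept runs from one cut vertex to the other; the unit edge closes it
    report = validate_polygon(kept)
    if not report.valid:
        raise ExcisionError(f"closure is not a valid polygon: {report.reason}")
    return LatticePolygon(kept, check=False)


@dataclass(frozen=True)
class CoreResult:
    """Outcome of the stochastic knotted-core search."""

    core_length: int
    fraction: float
    core: LatticePolygon
    original_length: int
    n_restarts: int
    accepted_excisions: int


def minimal_knotted_core(
    polygon: LatticePolygon,
    expected,
    n_restarts: int = 3,
    seed: int = 0,
    n_directions: int = 3,
    max_stale: int = 400,
    deterministic: bool = False,
) -> CoreResult:
    """Stochastic greedy excision search for the minimal knotted core.

    From each restart, candidate cut pairs are drawn uniformly at random
    (or largest-removal-first when ``deterministic``); an excision is
    accepted iff the certified Alexander determinant equals that of
    ``expected``.  Within a restart the length is monotonically
    non-increasing, and the cross-restart minimum is returned.  The core can
    never go below the knot's minimal lattice step number.
    """
    base = polygon
    cert0 = certify_knot(base, expected, n_directions=n_directions, seed=derive_seed(seed, 991))
    if not cert0.passed:
        raise ValueError(
            f"polygon is not certified as the expected knot "
            f"(determinants {cert0.determinants}, expected {cert0.expected_determinant})"
        )
    best = base
    accepted_total = 0
    for r in range(n_restarts):
        rng = np.random.default_rng(derive_seed(seed, r))
        cur = base
        stale = 0
        while stale < max_stale:
            cands = candidate_excisions(cur)
            if not cands:
                break
            if deterministic:
                # largest-removal-first: sort by removed arc length, descending
                n = cur.n

                def removed(pair):
                    d = abs(pair[0] - pair[1])
                    return max(min(d, n - d), n - min(d, n - d)) - 1

                cands.sort(key=lambda p: (-removed(p), p))
                order = cands
            else:
                order = [cands[k] for k in rng.permutation(len(cands))]
            progressed = False
            for i, j in order[: max(8, len(order) // 4)]:
                for keep in ("shorter", "longer"):
                    try:
                        cand = excise_once(cur, i, j, keep=keep)
                    except ExcisionError:
                        continue
                    if cand.n >= cur.n:
                        continue
                    cert = certify_knot(
                        cand, expected, n_directions=n_directions, seed=derive_seed(seed, 7000 + cand.n)
                    )
                    if cert.passed:
                        cur = cand
                        accepted_total += 1
                        progressed = True
                        break
                if progressed:
                    break
            if progressed:
                stale = 0
            else:
                stale += len(order)
        if cur.n < best.n:
            best = cur
        if deterministic:
            break  # deterministic heuristic is restart-invariant
    return CoreResult(
        core_length=best.n,
        fraction=best.n / base.n,
        core=best,
        original_length=base.n,
        n_restarts=n_restarts,
        accepted_excisions=accepted_total,
    )
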