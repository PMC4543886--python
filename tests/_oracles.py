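"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's optimized code paths: the pair
observables are recomputed with a naive double loop, and the equilibrium
stationary distribution is checked against an exhaustive enumeration of all
polygons that fit in a small box.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

_STEPS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def naive_pair_curves(vertices: np.ndarray, diag_w: float) -> tuple[np.ndarray, np.ndarray]:
    """P(s) and R(s) via direct enumeration of all unordered vertex pairs."""
    v = np.asarray(vertices)
    n = len(v)
    smax = n // 2
    w = np.zeros(smax + 1)
    rsum = np.zeros(smax + 1)
    cnt = np.zeros(smax + 1)
    for i in range(n):
        for j in range(i + 1, n):
            d = abs(i - j)
            s = min(d, n - d)
            dist = math.dist(v[i], v[j])
            rsum[s] += dist
            cnt[s] += 1
            if s >= 2:
                if abs(dist - 1.0) < 1e-12:
                    w[s] += 1.0
                elif abs(dist - math.sqrt(2)) < 1e-12:
                    w[s] += diag_w
    P = w[1:] / n
    R = rsum[1:] / np.maximum(cnt[1:], 1)
    return P, R


def enumerate_box_polygons(shape=(3, 3, 3)) -> dict[int, int]:
    """Count self-avoiding polygons (unrooted, unoriented) per length that
    fit inside a box of the given shape with coordinates >= 0.

    Each polygon is counted once: the walk starts at its lexicographically
    smallest vertex and its second vertex is constrained to be smaller than
    its last vertex, which fixes the root and orientation.
    """
    sites = [p for p in product(range(shape[0]), range(shape[1]), range(shape[2]))]
    site_set = set(sites)
    counts: dict[int, int] = {}

    def neighbors(p):
        for s in _STEPS:
            q = (p[0] + s[0], p[1] + s[1], p[2] + s[2])
            if q in site_set:
                yield q

    def dfs(start, path, visited):
        cur = path[-1]
        for q in neighbors(cur):
            if q == start and len(path) >= 4:
                # closing: orientation fixed by second < last vertex
                if path[1] < path[-1]:
                    counts[len(path)] = counts.get(len(path), 0) + 1
            if q in visited or q < start:
                continue
            visited.add(q)
            path.append(q)
            dfs(start, path, visited)
            path.pop()
            visited.remove(q)

    for start in sites:
        dfs(start, [start], {start})
    return counts
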