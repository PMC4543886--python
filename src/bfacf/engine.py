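"""BFACF Monte Carlo on self-avoiding lattice polygons.

The BFACF move set acts on a closed self-avoiding polygon by picking one of
the ``n`` edges uniformly at random and one of the 4 lattice directions
perpendicular to it, then pushing the edge one step that way.  Depending on
the local geometry the proposal is a corner flip (length change 0), an edge
extrusion (+2) or a hairpin retraction (-2).  The ergodicity classes of this
move set are exactly the knot types, so a trajectory can never change the
polygon's knot.

Two acceptance regimes are implemented:

* **equilibrium** — Metropolis–Hastings targeting the fugacity ensemble
  pi(omega) proportional to z^|omega| over polygons.  Because a specific
  (+2) move is proposed with probability 1/(4n) while its inverse (-2) is
  proposed with probability 1/(4(n+2)), the acceptance probabilities carry
  the length-dependent proposal correction:

      A(+2) = min(1, z^2 * n / (n + 2)),
      A(-2) = min(1, z^-2 * n / (n - 2)),   A(0) = 1.

* **annealing** — a raw acceptance triplet [p(-2), p(0), p(+2)]: every
  *feasible* proposal of class Delta is accepted with probability
  ``triplet[Delta]``, with no fugacity; the residual mass is the stay-put
  probability.  Run inside a confining sphere until a target length is
  reached, this grows a *BFACF globule* of fixed knot type.

The hot loop is a numba-compiled kernel over a doubly-linked vertex list
plus an occupancy grid, with a self-contained xorshift64* RNG so that runs
are bit-reproducible from an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
from numba import njit

from .polygon import LatticePolygon, SphericalConfinement

__all__ = [
    "Z_CRITICAL",
    "AnnealingTriplet",
    "FugacityParameter",
    "MoveProposal",
    "BfacfGlobule",
    "AnnealingError",
    "propose_move",
    "apply_move",
    "run_equilibrium",
    "run_annealing",
    "generate_ensemble",
    "shrink_search",
    "derive_seed",
]

# Critical fugacity 1/mu for Z^3 self-avoiding polygons (mu ~= 4.684); above
# this the equilibrium mean length diverges.
Z_CRITICAL = 0.2134


@dataclass(frozen=True)
class AnnealingTriplet:
    """Raw acceptance probabilities [p(-2), p(0), p(+2)] of the annealing regime."""

    p_minus2: float
    p_zero: float
    p_plus2: float

    def __post_init__(self) -> None:
        for name in ("p_minus2", "p_zero", "p_plus2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_minus2 + self.p_zero + self.p_plus2 > 1.0 + 1e-12:
            raise ValueError("triplet must sum to at most 1 (residual mass = stay-put)")

    @property
    def p_stay(self) -> float:
        return 1.0 - (self.p_minus2 + self.p_zero + self.p_plus2)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_minus2, self.p_zero, self.p_plus2)


@dataclass(frozen=True)
class FugacityParameter:
    """Per-bond fugacity z of the equilibrium regime, 0 <= z <= z_0."""

    z: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.z <= Z_CRITICAL:
            raise ValueError(f"fugacity z={self.z} outside [0, {Z_CRITICAL}]")


@dataclass(frozen=True)
class MoveProposal:
    """One BFACF proposal: an edge, a perpendicular direction, and its class."""

    edge_index: int
    direction: tuple[int, int, int]
    delta: int  # -2, 0, or +2
    feasible: bool
    reason: str | None = None
    # payload used by apply_move: varies by class
    _payload: tuple = field(default=(), repr=False)


@dataclass
class BfacfGlobule:
    """An annealed fixed-topology globule plus its generation provenance."""

    polygon: LatticePolygon
    knot: str
    triplet: AnnealingTriplet
    confinement: SphericalConfinement | None
    seed: int
    n_proposals: int
    counters: dict[str, int]
    fill_fraction: float | None = None


class AnnealingError(RuntimeError):
    """Raised when the proposal budget is exhausted before the target length."""

    def __init__(self, message: str, length_reached: int):
        super().__init__(message)
        self.length_reached = length_reached


# ---------------------------------------------------------------------------
# Pure-Python move mechanics (reference implementation / public per-move API)
# ---------------------------------------------------------------------------

_PERP = {0: (1, 2), 1: (0, 2), 2: (0, 1)}


def _perpendicular_directions(step: np.ndarray) -> list[tuple[int, int, int]]:
    axis = int(np.nonzero(step)[0][0])
    dirs = []
    for ax in _PERP[axis]:
        for s in (1, -1):
            u = [0, 0, 0]
            u[ax] = s
            dirs.append(tuple(u))
    return dirs


def _classify(
    polygon: LatticePolygon,
    i: int,
    u: tuple[int, int, int],
    confinement: SphericalConfinement | None,
) -> MoveProposal:
    v = polygon.vertices
    n = polygon.n
    a = v[i]
    b = v[(i + 1) % n]
    uarr = np.asarray(u, dtype=np.int64)
    ap = a + uarr
    bp = b + uarr
    prev_v = v[(i - 1) % n]
    next2_v = v[(i + 2) % n]
    occupied = {tuple(p) for p in v.tolist()}

    def admissible(p: np.ndarray) -> bool:
        return confinement is None or bool(confinement.contains(p[None, :])[0])

    a_is_prev = bool(np.all(ap == prev_v))
    b_is_next2 = bool(np.all(bp == next2_v))
    if a_is_prev and b_is_next2:
        feasible = n >= 6
        return MoveProposal(i, u, -2, feasible, None if feasible else "minimal polygon", ())
    if a_is_prev:
        ok = tuple(bp.tolist()) not in occupied and admissible(bp)
        return MoveProposal(i, u, 0, ok, None if ok else "target site blocked", ("a", tuple(bp.tolist())))
    if b_is_next2:
        ok = tuple(ap.tolist()) not in occupied and admissible(ap)
        return MoveProposal(i, u, 0, ok, None if ok else "target site blocked", ("b", tuple(ap.tolist())))
    ok = (
        tuple(ap.tolist()) not in occupied
        and tuple(bp.tolist()) not in occupied
        and admissible(ap)
        and admissible(bp)
    )
    return MoveProposal(
        i, u, 2, ok, None if ok else "target sites blocked", (tuple(ap.tolist()), tuple(bp.tolist()))
    )


def classify_move(
    polygon: LatticePolygon,
    edge_index: int,
    direction: tuple[int, int, int],
    confinement: SphericalConfinement | None = None,
) -> MoveProposal:
    """Classify the BFACF proposal (edge, perpendicular direction) explicitly."""
    return _classify(polygon, edge_index, direction, confinement)


def propose_move(
    polygon: LatticePolygon,
    rng: np.random.Generator,
    confinement: SphericalConfinement | None = None,
) -> MoveProposal:
    """Draw one uniform BFACF proposal (edge uniform among n, direction among 4)."""
    n = polygon.n
    i = int(rng.integers(n))
    step = polygon.vertices[(i + 1) % n] - polygon.vertices[i]
    dirs = _perpendicular_directions(step)
    u = dirs[int(rng.integers(4))]
    return _classify(polygon, i, u, confinement)


def apply_move(polygon: LatticePolygon, proposal: MoveProposal) -> LatticePolygon:
    """Apply a feasible proposal, returning the transformed polygon."""
    if not proposal.feasible:
        raise ValueError(f"cannot apply infeasible proposal: {proposal.reason}")
    v = polygon.vertices
    n = polygon.n
    i = proposal.edge_index
    if proposal.delta == -2:
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        keep[(i + 1) % n] = False
        return LatticePolygon(v[keep], check=False)
    if proposal.delta == 0:
        which, new_pt = proposal._payload
        out = v.copy()
        j = i if which == "a" else (i + 1) % n
        out[j] = new_pt
        return LatticePolygon(out, check=False)
    ap, bp = proposal._payload
    ins = np.array([ap, bp], dtype=np.int64)
    if i + 1 < n:
        out = np.insert(v, i + 1, ins, axis=0)
    else:  # inserting across the wrap point appends at the end
        out = np.concatenate([v, ins])
    return LatticePolygon(out, check=False)


# ---------------------------------------------------------------------------
# Seeded RNG helpers (xorshift64* / splitmix64)
# ---------------------------------------------------------------------------

_U64 = np.uint64
_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)


def derive_seed(base_seed: int, index: int) -> int:
    """Deterministic per-replicate stream seed from (base_seed, index)."""
    x = (int(base_seed) * 0x9E3779B97F4A7C15 + (index + 1) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    z = z ^ (z >> 31)
    return z or 1


def _rng_state(seed: int) -> np.ndarray:
    return np.array([derive_seed(seed, 0xA5A5)], dtype=np.uint64)


@njit(cache=True, inline="always")
def _rand_u64(rng):  # pragma: no cover - numba
    x = rng[0]
    x ^= x >> _U64(12)
    x ^= (x << _U64(25)) & _MASK
    x ^= x >> _U64(27)
    rng[0] = x
    return (x * _U64(2685821657736338717)) & _MASK


@njit(cache=True, inline="always")
def _rand_unit(rng):  # pragma: no cover - numba
    return (_rand_u64(rng) >> _U64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _randint(rng, n):  # pragma: no cover - numba
    # modulo with rejection to kill the (already tiny) modulo bias
    nn = _U64(n)
    lim = _MASK - (_MASK % nn)
    x = _rand_u64(rng)
    while x > lim:
        x = _rand_u64(rng)
    return np.int64(x % nn)


# ---------------------------------------------------------------------------
# Numba kernel over a doubly-linked vertex list + occupancy grid
# ---------------------------------------------------------------------------

_STATUS_DONE = 0
_STATUS_TARGET = 1
_STATUS_CAPACITY = 2


@njit(cache=True)
def _bfacf_kernel(
    coords,  # int64[cap, 3]
    nxt,  # int64[cap]
    prv,  # int64[cap]
    active,  # int64[cap]
    pos,  # int64[cap]
    free_stack,  # int64[cap]
    meta,  # int64[2]: n, free_top
    grid,  # uint8[G, G, G] occupancy
    adm,  # uint8[G, G, G] admissible sites (0 on the boundary shell)
    ox,
    oy,
    oz,
    rng,  # uint64[1]
    mode,  # 0 = equilibrium, 1 = annealing
    z,
    p_m2,
    p_0,
    p_p2,
    max_proposals,
    target_len,  # stop when n >= target_len (0 = never)
    counters,  # int64[8]
    sample_every,  # record length histogram every k proposals (0 = off)
    len_hist,  # int64[maxlen+1]
    track_best,  # 1 = record shortest polygon seen
    best_len,  # int64[1]
    best_verts,  # int64[cap, 3]
    bias_cx,  # radial-bias center (lattice coords)
    bias_cy,
    bias_cz,
    bias_r2,  # squared target radius of the soft radial bias
    bias_factor,  # acceptance multiplier for outward moves beyond bias_r2 (1 = off)
):  # pragma: no cover - numba
    z2 = z * z
    t = np.int64(0)
    status = _STATUS_DONE
    while t < max_proposals:
        t += 1
        n = meta[0]
        idx = _randint(rng, n)
        a = active[idx]
        b = nxt[a]
        ax, ay, az = coords[a, 0], coords[a, 1], coords[a, 2]
        bx, by, bz = coords[b, 0], coords[b, 1], coords[b, 2]
        ex, ey, ez = bx - ax, by - ay, bz - az
        # perpendicular direction: 4 choices
        r = np.int64(_rand_u64(rng) & _U64(3))
        ux = np.int64(0)
        uy = np.int64(0)
        uz = np.int64(0)
        if ex != 0:
            if r == 0:
                uy = 1
            elif r == 1:
                uy = -1
            elif r == 2:
                uz = 1
            else:
                uz = -1
        elif ey != 0:
            if r == 0:
                ux = 1
            elif r == 1:
                ux = -1
            elif r == 2:
                uz = 1
            else:
                uz = -1
        else:
            if r == 0:
                ux = 1
            elif r == 1:
                ux = -1
            elif r == 2:
                uy = 1
            else:
                uy = -1
        apx, apy, apz = ax + ux, ay + uy, az + uz
        bpx, bpy, bpz = bx + ux, by + uy, bz + uz
        p = prv[a]
        n2 = nxt[b]
        a_is_prev = coords[p, 0] == apx and coords[p, 1] == apy and coords[p, 2] == apz
        b_is_next2 = coords[n2, 0] == bpx and coords[n2, 1] == bpy and coords[n2, 2] == bpz

        if a_is_prev and b_is_next2:
            counters[0] += 1  # proposed -2
            if n >= 6:
                if mode == 0:
                    acc = n / ((n - 2) * z2) if z2 > 0 else 2.0
                else:
                    acc = p_m2
                if acc >= 1.0 or _rand_unit(rng) < acc:
                    # delete a and b
                    nxt[p] = n2
                    prv[n2] = p
                    grid[ax + ox, ay + oy, az + oz] = 0
                    grid[bx + ox, by + oy, bz + oz] = 0
                    for dead in (a, b):
                        i2 = pos[dead]
                        last = active[meta[0] - 1]
                        active[i2] = last
                        pos[last] = i2
                        meta[0] -= 1
                        free_stack[meta[1]] = dead
                        meta[1] += 1
                    counters[3] += 1
        elif a_is_prev or b_is_next2:
            counters[1] += 1  # proposed 0
            if a_is_prev:
                tx, ty, tz = bpx, bpy, bpz
                node = a
                cx, cy, cz = ax, ay, az
            else:
                tx, ty, tz = apx, apy, apz
                node = b
                cx, cy, cz = bx, by, bz
            gi, gj, gk = tx + ox, ty + oy, tz + oz
            if adm[gi, gj, gk] == 1 and grid[gi, gj, gk] == 0:
                if mode == 0:
                    acc = 2.0
                else:
                    acc = p_0
                if bias_factor < 1.0:
                    rt2 = (tx - bias_cx) ** 2 + (ty - bias_cy) ** 2 + (tz - bias_cz) ** 2
                    rc2 = (cx - bias_cx) ** 2 + (cy - bias_cy) ** 2 + (cz - bias_cz) ** 2
                    if rt2 > bias_r2 and rt2 > rc2:
                        acc = acc * bias_factor
                if acc >= 1.0 or _rand_unit(rng) < acc:
                    grid[cx + ox, cy + oy, cz + oz] = 0
                    grid[gi, gj, gk] = 1
                    coords[node, 0] = tx
                    coords[node, 1] = ty
                    coords[node, 2] = tz
                    counters[4] += 1
            elif adm[gi, gj, gk] == 0:
                counters[6] += 1
        else:
            counters[2] += 1  # proposed +2
            g1i, g1j, g1k = apx + ox, apy + oy, apz + oz
            g2i, g2j, g2k = bpx + ox, bpy + oy, bpz + oz
            adm_ok = adm[g1i, g1j, g1k] == 1 and adm[g2i, g2j, g2k] == 1
            if not adm_ok:
                counters[6] += 1
            elif grid[g1i, g1j, g1k] == 0 and grid[g2i, g2j, g2k] == 0:
                if meta[1] < 2:
                    status = _STATUS_CAPACITY
                    t -= 1
                    break
                if mode == 0:
                    acc = z2 * n / (n + 2)
                else:
                    acc = p_p2
                if bias_factor < 1.0:
                    ra2 = (apx - bias_cx) ** 2 + (apy - bias_cy) ** 2 + (apz - bias_cz) ** 2
                    rb2 = (bpx - bias_cx) ** 2 + (bpy - bias_cy) ** 2 + (bpz - bias_cz) ** 2
                    rm2 = ra2 if ra2 > rb2 else rb2
                    if rm2 > bias_r2:
                        acc = acc * bias_factor
                if acc >= 1.0 or _rand_unit(rng) < acc:
                    meta[1] -= 1
                    na = free_stack[meta[1]]
                    meta[1] -= 1
                    nb = free_stack[meta[1]]
                    coords[na, 0] = apx
                    coords[na, 1] = apy
                    coords[na, 2] = apz
                    coords[nb, 0] = bpx
                    coords[nb, 1] = bpy
                    coords[nb, 2] = bpz
                    nxt[a] = na
                    prv[na] = a
                    nxt[na] = nb
                    prv[nb] = na
                    nxt[nb] = b
                    prv[b] = nb
                    grid[g1i, g1j, g1k] = 1
                    grid[g2i, g2j, g2k] = 1
                    active[meta[0]] = na
                    pos[na] = meta[0]
                    meta[0] += 1
                    active[meta[0]] = nb
                    pos[nb] = meta[0]
                    meta[0] += 1
                    counters[5] += 1

        if sample_every > 0 and t % sample_every == 0:
            ln = meta[0]
            if ln < len_hist.shape[0]:
                len_hist[ln] += 1
        if track_best == 1 and meta[0] < best_len[0]:
            bl = meta[0]
            best_len[0] = bl
            node = active[0]
            for w in range(bl):
                best_verts[w, 0] = coords[node, 0]
                best_verts[w, 1] = coords[node, 1]
                best_verts[w, 2] = coords[node, 2]
                node = nxt[node]
        if target_len > 0 and meta[0] >= target_len:
            status = _STATUS_TARGET
            break
    counters[7] += t
    return status


class _SimState:
    """Python-side owner of the kernel arrays for one polygon trajectory."""

    def __init__(
        self,
        polygon: LatticePolygon,
        confinement: SphericalConfinement | None,
        capacity: int,
        seed: int,
        margin: int = 24,
        allow_outside: bool = False,
    ):
        self.confinement = confinement
        self.allow_outside = allow_outside
        self.rng = _rng_state(seed)
        self.counters = np.zeros(8, dtype=np.int64)
        self._build(polygon, capacity, margin)

    # -- grid / array construction -------------------------------------

    def _build(self, polygon: LatticePolygon, capacity: int, margin: int) -> None:
        v = polygon.vertices
        n = v.shape[0]
        capacity = max(capacity, n + 4)
        conf = self.confinement
        if conf is not None:
            cx, cy, cz = (int(round(c)) for c in conf.center)
            half = int(math.ceil(conf.radius)) + 3
            if self.allow_outside:
                # grid must also cover the (possibly exterior) polygon
                ext = int(max(np.abs(v - np.array([cx, cy, cz])).max(), half)) + 3
                half = max(half, ext)
            lo = np.array([cx - half, cy - half, cz - half], dtype=np.int64)
            G = 2 * half + 1
        else:
            vlo = v.min(axis=0) - margin
            vhi = v.max(axis=0) + margin
            G = int((vhi - vlo).max()) + 1
            lo = vlo - (G - (vhi - vlo)) // 2
        self.lo = lo
        self.G = G
        self.grid = np.zeros((G, G, G), dtype=np.uint8)
        adm = np.zeros((G, G, G), dtype=np.uint8)
        if conf is not None:
            xs = np.arange(G)
            gx, gy, gz = np.meshgrid(xs, xs, xs, indexing="ij")
            pts = np.stack([gx + lo[0], gy + lo[1], gz + lo[2]], axis=-1)
            adm[conf.contains(pts)] = 1
        else:
            adm[:] = 1
        # 2-cell hard shell so neighbor lookups never leave the grid
        adm[:2, :, :] = 0
        adm[-2:, :, :] = 0
        adm[:, :2, :] = 0
        adm[:, -2:, :] = 0
        adm[:, :, :2] = 0
        adm[:, :, -2:] = 0
        self.adm = adm

        self.coords = np.zeros((capacity, 3), dtype=np.int64)
        self.nxt = np.zeros(capacity, dtype=np.int64)
        self.prv = np.zeros(capacity, dtype=np.int64)
        self.active = np.zeros(capacity, dtype=np.int64)
        self.pos = np.zeros(capacity, dtype=np.int64)
        self.free_stack = np.zeros(capacity, dtype=np.int64)
        self.meta = np.zeros(2, dtype=np.int64)
        self.capacity = capacity

        self.coords[:n] = v
        ids = np.arange(n, dtype=np.int64)
        self.nxt[:n] = np.roll(ids, -1)
        self.prv[:n] = np.roll(ids, 1)
        self.active[:n] = ids
        self.pos[:n] = ids
        nfree = capacity - n
        self.free_stack[:nfree] = np.arange(capacity - 1, n - 1, -1, dtype=np.int64)
        self.meta[0] = n
        self.meta[1] = nfree
        gidx = v - lo
        if np.any(gidx < 2) or np.any(gidx >= G - 2):
            raise ValueError("polygon does not fit inside the simulation grid")
        if conf is not None and not self.allow_outside and not np.all(conf.contains(v)):
            raise ValueError("seed polygon does not fit inside the confinement")
        self.grid[gidx[:, 0], gidx[:, 1], gidx[:, 2]] = 1

    @property
    def n(self) -> int:
        return int(self.meta[0])

    def polygon(self) -> LatticePolygon:
        n = self.n
        out = np.empty((n, 3), dtype=np.int64)
        node = int(self.active[0])
        for w in range(n):
            out[w] = self.coords[node]
            node = int(self.nxt[node])
        return LatticePolygon(out, check=False)

    def recenter_if_needed(self, margin: int = 24) -> None:
        """Re-box an unconfined polygon when it drifts near the grid shell."""
        if self.confinement is not None:
            return
        poly = self.polygon()
        gidx = poly.vertices - self.lo
        if np.any(gidx < 6) or np.any(gidx >= self.G - 6):
            cap = self.capacity
            rng_save = self.rng
            counters_save = self.counters
            self._build(poly, cap, margin)
            self.rng = rng_save
            self.counters = counters_save

    def grow_capacity(self) -> None:
        poly = self.polygon()
        cap = max(self.capacity * 2, self.capacity + 512)
        rng_save = self.rng
        counters_save = self.counters
        conf_margin = 24 if self.confinement is None else 0
        self._build(poly, cap, conf_margin or 24)
        self.rng = rng_save
        self.counters = counters_save

    # -- kernel driver --------------------------------------------------

    def run(
        self,
        mode: int,
        n_proposals: int,
        z: float = 0.0,
        triplet: tuple[float, float, float] = (0.0, 0.0, 0.0),
        target_len: int = 0,
        sample_every: int = 0,
        len_hist: np.ndarray | None = None,
        track_best: bool = False,
        best_len: np.ndarray | None = None,
        best_verts: np.ndarray | None = None,
        chunk: int = 2_000_000,
        bias_r2: float = 0.0,
        bias_factor: float = 1.0,
    ) -> int:
        if len_hist is None:
            len_hist = np.zeros(1, dtype=np.int64)
        if best_len is None:
            best_len = np.array([np.iinfo(np.int64).max], dtype=np.int64)
        if best_verts is None:
            best_verts = np.zeros((1, 3), dtype=np.int64)
        done = 0
        status = _STATUS_DONE
        while done < n_proposals:
            todo = min(chunk, n_proposals - done)
            before = int(self.counters[7])
            status = _bfacf_kernel(
                self.coords,
                self.nxt,
                self.prv,
                self.active,
                self.pos,
                self.free_stack,
                self.meta,
                self.grid,
                self.adm,
                -int(self.lo[0]),
                -int(self.lo[1]),
                -int(self.lo[2]),
                self.rng,
                mode,
                z,
                triplet[0],
                triplet[1],
                triplet[2],
                todo,
                target_len,
                self.counters,
                sample_every,
                len_hist,
                1 if track_best else 0,
                best_len,
                best_verts,
                np.int64(round(self.confinement.center[0])) if self.confinement else np.int64(0),
                np.int64(round(self.confinement.center[1])) if self.confinement else np.int64(0),
                np.int64(round(self.confinement.center[2])) if self.confinement else np.int64(0),
                bias_r2,
                bias_factor,
            )
            done += int(self.counters[7]) - before
            if status == _STATUS_TARGET:
                break
            if status == _STATUS_CAPACITY:
                self.grow_capacity()
                continue
            self.recenter_if_needed()
        return status

    def counters_dict(self) -> dict[str, int]:
        c = self.counters
        return {
            "proposed_minus2": int(c[0]),
            "proposed_zero": int(c[1]),
            "proposed_plus2": int(c[2]),
            "accepted_minus2": int(c[3]),
            "accepted_zero": int(c[4]),
            "accepted_plus2": int(c[5]),
            "inadmissible": int(c[6]),
            "proposals": int(c[7]),
        }


def _as_seed(rng) -> int:
    if isinstance(rng, (int, np.integer)):
        return int(rng)
    if isinstance(rng, np.random.Generator):
        return int(rng.integers(1, 2**63 - 1))
    raise TypeError("rng must be an integer seed or numpy Generator")


def run_equilibrium(
    polygon: LatticePolygon,
    z: float | FugacityParameter,
    n_steps: int,
    rng: int | np.random.Generator,
    confinement: SphericalConfinement | None = None,
    check_every: int | None = None,
) -> LatticePolygon:
    """Run the equilibrium (fugacity) regime for ``n_steps`` proposals.

    One step is one proposal, accepted or not.  The stationary distribution
    is pi(omega) ~ z^|omega| over self-avoiding polygons (restricted to the
    confinement when one is given); the knot class is conserved.  When
    unconfined, the simulation box is re-centered around the polygon as it
    drifts, which confines it to a very large moving box — immaterial at the
    short equilibrium lengths used here.
    """
    if isinstance(z, FugacityParameter):
        zv = z.z
    else:
        zv = float(z)
        FugacityParameter(zv)  # validate range
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if n_steps == 0:
        return polygon
    state = _SimState(polygon, confinement, capacity=polygon.n + 2048, seed=_as_seed(rng))
    if check_every:
        done = 0
        while done < n_steps:
            todo = min(check_every, n_steps - done)
            state.run(mode=0, n_proposals=todo, z=zv)
            done += todo
            report = state.polygon().validate()
            if not report.valid:  # pragma: no cover - defensive
                raise RuntimeError(f"invariant violation mid-run: {report.reason}")
    else:
        state.run(mode=0, n_proposals=n_steps, z=zv)
    out = state.polygon()
    assert out.validate().valid
    return out


def equilibrium_length_histogram(
    polygon: LatticePolygon,
    z: float,
    n_steps: int,
    seed: int,
    confinement: SphericalConfinement | None = None,
    sample_every: int = 50,
    max_length: int = 512,
) -> np.ndarray:
    """Length-class occupation counts along one equilibrium trajectory.

    Used by the exact-enumeration stationarity oracle: in a small confining
    region the empirical length distribution must converge to
    P(n) ~ C(n) z^n with C(n) the number of polygons of length n that fit.
    """
    state = _SimState(polygon, confinement, capacity=polygon.n + max_length + 64, seed=seed)
    hist = np.zeros(max_length + 1, dtype=np.int64)
    state.run(mode=0, n_proposals=n_steps, z=z, sample_every=sample_every, len_hist=hist)
    return hist


def run_annealing(
    polygon: LatticePolygon,
    triplet: AnnealingTriplet,
    confinement: SphericalConfinement | None,
    target_length: int,
    max_proposals: int,
    rng: int | np.random.Generator,
    knot: str = "?",
) -> BfacfGlobule:
    """Grow a BFACF globule with the raw-triplet annealing regime.

    Every feasible proposal of class Delta is accepted with probability
    ``triplet[Delta]``; the run stops at the first proposal after which the
    length reaches ``target_length``.  Raises :class:`AnnealingError` with
    the length reached if the proposal budget is exhausted first (the
    signature of a triplet that cannot fill the sphere).
    """
    if target_length % 2 != 0 or target_length < polygon.n:
        raise ValueError("target_length must be even and >= seed length")
    seed = _as_seed(rng)
    state = _SimState(polygon, confinement, capacity=target_length + 8, seed=seed)
    status = state.run(
        mode=1,
        n_proposals=max_proposals,
        triplet=triplet.as_tuple(),
        target_len=target_length,
    )
    out = state.polygon()
    report = out.validate()
    if not report.valid:  # pragma: no cover - defensive
        raise RuntimeError(f"invariant violation after annealing: {report.reason}")
    if status != _STATUS_TARGET and out.n < target_length:
        raise AnnealingError(
            f"annealing stalled at length {out.n} < {target_length} "
            f"after {int(state.counters[7])} proposals",
            out.n,
        )
    fill = None
    if confinement is not None:
        fill = out.n / confinement.lattice_site_count()
    return BfacfGlobule(
        polygon=out,
        knot=knot,
        triplet=triplet,
        confinement=confinement,
        seed=seed,
        n_proposals=int(state.counters[7]),
        counters=state.counters_dict(),
        fill_fraction=fill,
    )


def compress_into_sphere(
    polygon: LatticePolygon,
    confinement: SphericalConfinement,
    seed: int,
    triplet: "AnnealingTriplet | None" = None,
    shrink_z: float = 0.05,
    max_cycles: int = 600,
) -> LatticePolygon:
    """Drive a polygon entirely inside a target sphere, conserving its knot.

    Large composite seeds do not fit the confining sphere as constructed, so
    they are funneled in by alternating growth and shrinkage cycles under a
    *soft radial bias*: any proposal that would move material outward beyond
    the target radius has its acceptance multiplied by a factor that is
    tightened from 0.25 to 0 over the cycles, while material inside the
    sphere stays fully mobile.  Growth (raw-triplet annealing to 1.5x the
    current length) provides the slack the chain needs to rearrange;
    low-fugacity equilibrium shrinkage removes it again.  All moves are
    ordinary BFACF moves, so the knot class is conserved throughout.
    """
    trip = (triplet or AnnealingTriplet(0.10, 0.25, 0.25)).as_tuple()
    center = np.asarray(confinement.center)
    bias_r2 = float(confinement.radius) ** 2
    poly = polygon.translated(np.round(center - polygon.centroid()).astype(np.int64))
    cap = max(5000, 2 * poly.n + 1024)
    for it in range(1, max_cycles + 1):
        if np.all(confinement.contains(poly.vertices)):
            return poly
        # soften the bias while the polygon is still far outside: outward
        # moves must stay possible for the chain to unfold on its way in
        r_now = poly.max_radius(confinement.center)
        if r_now > 2.0 * confinement.radius:
            bias = 0.25
        elif r_now > 1.15 * confinement.radius:
            bias = 0.05
        else:
            bias = 0.0
        grow = _SimState(poly, None, capacity=cap, seed=derive_seed(seed, 2 * it))
        grow.run(
            mode=1,
            n_proposals=12_000_000,
            triplet=trip,
            target_len=min(int(poly.n * 1.5), cap - 512),
            bias_r2=bias_r2,
            bias_factor=bias,
            chunk=1_000_000,
        )
        shrink = _SimState(grow.polygon(), None, capacity=cap, seed=derive_seed(seed, 2 * it + 1))
        target = poly.n
        for _ in range(40):
            if shrink.n <= target:
                break
            shrink.run(mode=0, n_proposals=1_000_000, z=shrink_z, bias_r2=bias_r2, bias_factor=bias)
        poly = shrink.polygon()
    raise AnnealingError(
        f"could not compress polygon to radius {confinement.radius} "
        f"(stuck at {poly.max_radius(confinement.center):.2f})",
        poly.n,
    )


def shrink_search(
    polygon: LatticePolygon,
    z: float = 0.02,
    n_restarts: int = 10,
    proposals_per_restart: int = 1_000_000,
    seed: int = 0,
) -> tuple[int, LatticePolygon]:
    """Track the shortest polygon seen along low-fugacity trajectories.

    Restarts from the input polygon ``n_restarts`` times with independent
    RNG streams; since BFACF conserves the knot class, the record is an
    upper bound on the knot's minimal lattice step number that converges to
    it as restarts accumulate.
    """
    best_n = polygon.n
    best_poly = polygon
    for k in range(n_restarts):
        state = _SimState(polygon, None, capacity=polygon.n + 1024, seed=derive_seed(seed, k))
        blen = np.array([best_n], dtype=np.int64)
        bverts = np.zeros((polygon.n + 1024, 3), dtype=np.int64)
        state.run(
            mode=0,
            n_proposals=proposals_per_restart,
            z=z,
            track_best=True,
            best_len=blen,
            best_verts=bverts,
        )
        if int(blen[0]) < best_n:
            best_n = int(blen[0])
            best_poly = LatticePolygon(bverts[:best_n].copy())
    return best_n, best_poly


def generate_ensemble(
    knot,
    triplet: AnnealingTriplet,
    confinement: SphericalConfinement | None,
    target_length: int,
    n_conformations: int,
    base_seed: int,
    randomize_steps: int = 100_000,
    randomize_z: float = 0.1,
    max_proposals: int = 400_000_000,
    certify_every: int = 0,
    seed_polygon: LatticePolygon | None = None,
) -> list[BfacfGlobule]:
    """Generate an ensemble of BFACF globules of one knot type.

    Each replicate starts from the knot's reference embedding, randomizes it
    with ``randomize_steps`` equilibrium proposals at ``randomize_z``
    (erasing the seed geometry without changing the knot), translates its
    centroid to the confinement center (compressing with a ratcheting sphere
    first if the randomized seed does not fit), then anneals with the raw
    triplet until ``target_length``.  Replicate k uses an independent RNG
    stream derived from (base_seed, k), so the ensemble is reproducible
    regardless of execution order.
    """
    from .seeds import KnotId, minimal_embedding  # runtime import avoids a cycle

    if n_conformations < 1:
        raise ValueError("n_conformations must be >= 1")
    if isinstance(knot, str):
        knot = KnotId.parse(knot)
    if seed_polygon is None:
        seed_polygon = minimal_embedding(knot)
    confined_template: LatticePolygon | None = None
    if confinement is not None and seed_polygon.max_radius(confinement.center) > confinement.radius:
        # seeds larger than the sphere (big connected sums) are funneled in
        # once; each replicate then re-randomizes the template inside the
        # sphere with its own stream before annealing
        centered = seed_polygon.translated(
            np.round(np.asarray(confinement.center) - seed_polygon.centroid()).astype(np.int64)
        )
        if centered.max_radius(confinement.center) > confinement.radius:
            confined_template = compress_into_sphere(
                centered, confinement, seed=derive_seed(base_seed, 0xC0), triplet=triplet
            )
        else:
            confined_template = centered
    out: list[BfacfGlobule] = []
    for k in range(n_conformations):
        rep_seed = derive_seed(base_seed, k)
        if confined_template is None:
            randomized = run_equilibrium(seed_polygon, randomize_z, randomize_steps, rep_seed)
            if confinement is not None:
                center = np.asarray(confinement.center)
                shift = np.round(center - randomized.centroid()).astype(np.int64)
                randomized = randomized.translated(shift)
                if randomized.max_radius(confinement.center) > confinement.radius:
                    randomized = compress_into_sphere(
                        randomized, confinement, seed=derive_seed(rep_seed, 1), triplet=triplet
                    )
        else:
            randomized = run_equilibrium(
                confined_template, randomize_z, randomize_steps, rep_seed, confinement=confinement
            )
        globule = run_annealing(
            randomized,
            triplet,
            confinement,
            target_length,
            max_proposals,
            derive_seed(rep_seed, 2),
            knot=str(knot),
        )
        if certify_every and k % certify_every == 0:
            from .invariants import certify_knot

            cert = certify_knot(globule.polygon, knot, n_directions=1, seed=derive_seed(rep_seed, 3))
            if not cert.passed:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"knot class not conserved for replicate {k}: "
                    f"determinants {cert.determinants}, expected {cert.expected_determinant}"
                )
        out.append(globule)
    return out
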