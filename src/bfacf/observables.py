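"""Contact probability P(s) and mean end-to-end distance R(s) of polygons.

For a closed polygon of n vertices, the arc (genomic) distance of a vertex
pair is the cyclic minimum of the two arc lengths, s in [1, n/2].  Following
the Hi-C-style scoring, a pair at arc distance s >= 2 contributes contact
weight 1 when the two vertices are lattice nearest neighbors (Euclidean
distance 1) and a reduced weight (default 1/sqrt(2)) when they are diagonal
neighbors (distance sqrt(2)); chain neighbors (s = 1) are excluded.  The
contact probability is the summed weight at s divided by the total number
of occupied vertices n — not a true probability normalization, but constant
factors cancel in the log-log slope.  R(s) is the plain mean Euclidean
distance over all pairs at arc distance s.

Slopes are ordinary least squares of log10(value) on log10(s) over integer
s in a stated fit range (default [9, 55]); ensemble uncertainties are
reported both as the OLS standard error on the averaged curve and as a
seeded bootstrap over conformations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit
from scipy import stats

from .polygon import LatticePolygon

__all__ = [
    "ContactCurve",
    "SlopeFit",
    "DEFAULT_DIAGONAL_WEIGHT",
    "DEFAULT_FIT_RANGE",
    "contact_curve",
    "end_to_end_curve",
    "ensemble_average",
    "fit_loglog_slope",
    "bootstrap_slope",
]

#: Weight for diagonal (distance sqrt(2)) contacts.
DEFAULT_DIAGONAL_WEIGHT = 1.0 / math.sqrt(2.0)

#: Arc-distance fit window for the log-log slope.
DEFAULT_FIT_RANGE = (9, 55)


@dataclass(frozen=True)
class ContactCurve:
    """Per-arc-distance observables of one conformation or an ensemble mean.

    ``P[k]`` and ``R[k]`` correspond to arc distance ``s[k]``; ``n_pairs``
    counts the vertex pairs at each s in a single conformation, and
    ``n_conformations`` tells how many conformations were averaged.
    """

    s: np.ndarray
    P: np.ndarray
    R: np.ndarray
    n_pairs: np.ndarray
    n: int
    diagonal_weight: float = DEFAULT_DIAGONAL_WEIGHT
    n_conformations: int = 1

    def __post_init__(self) -> None:
        if not (len(self.s) == len(self.P) == len(self.R) == len(self.n_pairs)):
            raise ValueError("curve arrays must have equal length")


@dataclass(frozen=True)
class SlopeFit:
    """OLS log-log slope over a stated s-range, with SE and 95% CI."""

    slope: float
    stderr: float
    ci95: tuple[float, float]
    s_min: int
    s_max: int
    n_points: int
    which: str
    intercept: float
    bootstrap_se: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.slope <= hi):
            raise ValueError("confidence interval must contain the slope")
        if self.s_min >= self.s_max:
            raise ValueError("fit range must satisfy s_min < s_max")


@njit(cache=True)
def _pair_scan(v, diag_w):  # pragma: no cover - numba
    n = v.shape[0]
    smax = n // 2
    w = np.zeros(smax + 1)
    rsum = np.zeros(smax + 1)
    npairs = np.zeros(smax + 1, dtype=np.int64)
    for s in range(1, smax + 1):
        imax = n if 2 * s < n else n // 2
        for i in range(imax):
            j = i + s
            if j >= n:
                j -= n
            dx = v[i, 0] - v[j, 0]
            dy = v[i, 1] - v[j, 1]
            dz = v[i, 2] - v[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            rsum[s] += math.sqrt(d2)
            npairs[s] += 1
            if s >= 2:
                if d2 == 1:
                    w[s] += 1.0
                elif d2 == 2:
                    w[s] += diag_w
    return w, rsum, npairs


def contact_curve(
    polygon: LatticePolygon, diagonal_weight: float = DEFAULT_DIAGONAL_WEIGHT
) -> ContactCurve:
    """Contact probability and end-to-end distance curves of one polygon.

    P(s) = (summed contact weight over pairs at arc distance s) / n, with
    contacts scored 1 at Euclidean distance 1 and ``diagonal_weight`` at
    sqrt(2); pairs at s = 1 are chain neighbors and contribute nothing.
    R(s) is the mean Euclidean distance over the same pairs.
    """
    v = polygon.vertices
    w, rsum, npairs = _pair_scan(v, float(diagonal_weight))
    n = polygon.n
    s = np.arange(1, n // 2 + 1)
    return ContactCurve(
        s=s,
        P=w[1:] / n,
        R=rsum[1:] / np.maximum(npairs[1:], 1),
        n_pairs=npairs[1:],
        n=n,
        diagonal_weight=diagonal_weight,
    )


def end_to_end_curve(polygon: LatticePolygon) -> ContactCurve:
    """Curve whose R component is the mean end-to-end distance per s."""
    return contact_curve(polygon)


def ensemble_average(curves: Sequence[ContactCurve]) -> ContactCurve:
    """Pointwise arithmetic mean of P(s) and R(s) over equal-length polygons."""
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one curve")
    n = curves[0].n
    if any(c.n != n for c in curves):
        raise ValueError("cannot average curves of mixed polygon lengths")
    P = np.mean([c.P for c in curves], axis=0)
    R = np.mean([c.R for c in curves], axis=0)
    total = sum(c.n_conformations for c in curves)
    return ContactCurve(
        s=curves[0].s.copy(),
        P=P,
        R=R,
        n_pairs=curves[0].n_pairs.copy(),
        n=n,
        diagonal_weight=curves[0].diagonal_weight,
        n_conformations=total,
    )


def _curve_values(curve: ContactCurve, which: str) -> np.ndarray:
    if which == "P":
        return curve.P
    if which == "R":
        return curve.R
    raise ValueError("which must be 'P' or 'R'")


def fit_loglog_slope(
    curve: ContactCurve,
    s_min: int = DEFAULT_FIT_RANGE[0],
    s_max: int = DEFAULT_FIT_RANGE[1],
    which: str = "P",
    bootstrap_se: float | None = None,
) -> SlopeFit:
    """OLS slope of log10(value) on log10(s) over integer s in [s_min, s_max]."""
    if s_min >= s_max:
        raise ValueError("s_min must be < s_max")
    values = _curve_values(curve, which)
    mask = (curve.s >= s_min) & (curve.s <= s_max)
    s = curve.s[mask]
    y = values[mask]
    if len(s) < 3:
        raise ValueError(f"fewer than 3 points in fit range [{s_min}, {s_max}]")
    if np.any(y <= 0):
        raise ValueError("nonpositive values in fit range; cannot take log")
    res = stats.linregress(np.log10(s), np.log10(y))
    df = len(s) - 2
    tcrit = stats.t.ppf(0.975, df) if df > 0 else np.inf
    half = tcrit * res.stderr if np.isfinite(tcrit) else 0.0
    return SlopeFit(
        slope=float(res.slope),
        stderr=float(res.stderr),
        ci95=(float(res.slope - half), float(res.slope + half)),
        s_min=int(s_min),
        s_max=int(s_max),
        n_points=int(len(s)),
        which=which,
        intercept=float(res.intercept),
        bootstrap_se=bootstrap_se,
    )


def bootstrap_slope(
    curves: Sequence[ContactCurve],
    which: str = "P",
    s_min: int = DEFAULT_FIT_RANGE[0],
    s_max: int = DEFAULT_FIT_RANGE[1],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Bootstrap (over conformations) mean and SE of the ensemble slope.

    Resamples the conformations with replacement ``n_boot`` times, averages
    the resampled curves, and fits the slope each time.  Returns the mean
    and standard deviation of the bootstrap slope distribution.
    """
    curves = list(curves)
    k = len(curves)
    if k < 2:
        raise ValueError("bootstrap needs at least 2 conformations")
    Pmat = np.array([_curve_values(c, which) for c in curves])
    s_all = curves[0].s
    mask = (s_all >= s_min) & (s_all <= s_max)
    logs = np.log10(s_all[mask])
    rng = np.random.default_rng(seed)
    slopes = []
    A = np.column_stack([logs, np.ones_like(logs)])
    pinv = np.linalg.pinv(A)
    for _b in range(n_boot):
        idx = rng.integers(0, k, size=k)
        mean_curve = Pmat[idx].mean(axis=0)[mask]
        if np.all(mean_curve > 0):
            slopes.append((pinv @ np.log10(mean_curve))[0])
        else:  # sparse small-ensemble curves: fit the positive points only
            ok = mean_curve > 0
            if ok.sum() < 3:
                continue
            Ao = A[ok]
            coef, *_ = np.linalg.lstsq(Ao, np.log10(mean_curve[ok]), rcond=None)
            slopes.append(coef[0])
    if len(slopes) < 2:
        raise ValueError("bootstrap failed: too few resamples with positive curves")
    arr = np.asarray(slopes)
    return float(arr.mean()), float(arr.std(ddof=1))
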