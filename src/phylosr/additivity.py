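"""Deviation from additivity of substitution-rate functions.

In a homogeneous model every SR function reduces to a univariate function
``D(t)`` of evolutionary time, and it is affine-additive iff ``D(t) = a t + b``
with ``a > 0``.  The *deviation from additivity* of ``D`` over an interval
``[t0, t1]`` is the slope-normalized minimax distance to the nearest affine
function:

    dev(D, [t0, t1]) = inf_{a>0, b}  max_{t in [t0,t1]} |D(t) - a t - b| / a .

Normalizing by the slope expresses the deviation in time units, which makes
it directly comparable to edge lengths: if the deviation is below half the
minimal edge time of a tree whose inter-leaf times all fall in ``[t0, t1]``,
the induced dissimilarity map is near-additive and robust distance methods
(four-point, neighbor joining) recover the topology.

When ``D`` does not cross its own linear interpolation inside the interval
(in particular when it is concave or convex, as the JC distance is under K2P
with R > 1/2), the optimal slope is the interpolation slope ``A`` and the
minimax fit is the interpolation line shifted by half the maximal gap ``X``,
giving the closed form ``dev = X / (2 A)``.  Otherwise a nested numeric
minimax is used: for fixed slope the optimal intercept is the Chebyshev
center of the residuals, and the slope is optimized by a bounded 1-D search
with a dense-scan fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import InvalidInputError
from .sr import JC, SRFunction, delta_jc_derivative

__all__ = [
    "Interval",
    "AffineFit",
    "DeviationResult",
    "linear_interpolation",
    "deviation_from_additivity",
    "deviation_bound",
    "consistency_check",
    "consistency_region",
]

_GRID_POINTS = 2001
_CURVATURE_GRID = 512


@dataclass(frozen=True)
class Interval:
    """A time interval [t0, t1] of inter-leaf distances, 0 <= t0 < t1."""

    t0: float
    t1: float

    def __post_init__(self):
        if not (0 <= self.t0 < self.t1):
            raise InvalidInputError(f"require 0 <= t0 < t1, got [{self.t0}, {self.t1}]")

    @property
    def width(self) -> float:
        return self.t1 - self.t0


@dataclass(frozen=True)
class AffineFit:
    """An affine function a*t + b with positive slope."""

    a: float
    b: float

    def __call__(self, t):
        return self.a * np.asarray(t, dtype=float) + self.b


@dataclass(frozen=True)
class DeviationResult:
    """Minimax affine fit and the resulting deviation (in time units)."""

    fit: AffineFit
    dev: float
    argmax_t: float
    method: str  # "closed_form" | "numeric"


def _as_curve(delta, R: float) -> Callable:
    """Normalize an SRFunction or plain callable to a function of t."""
    if isinstance(delta, SRFunction):
        return lambda t: delta.from_time(R, t)
    return delta


def _coerce_interval(interval) -> Interval:
    if isinstance(interval, Interval):
        return interval
    t0, t1 = interval
    return Interval(float(t0), float(t1))


def linear_interpolation(delta, R: float, interval) -> AffineFit:
    """Chord of the SR curve through its endpoint values on the interval.

    A = (D(t1) - D(t0)) / (t1 - t0),  B = (t1 D(t0) - t0 D(t1)) / (t1 - t0).
    """
    iv = _coerce_interval(interval)
    f = _as_curve(delta, R)
    d0, d1 = float(f(iv.t0)), float(f(iv.t1))
    A = (d1 - d0) / iv.width
    B = (iv.t1 * d0 - iv.t0 * d1) / iv.width
    return AffineFit(A, B)


def _check_monotone(y: np.ndarray) -> None:
    if np.any(np.diff(y) <= 0):
        raise InvalidInputError("SR curve must be strictly increasing on the interval")


def _refine_extremum(f: Callable, t_lo: float, t_hi: float, sign: float) -> tuple[float, float]:
    """Locate an extremum of f on [t_lo, t_hi]; sign=+1 for max, -1 for min."""
    res = minimize_scalar(lambda t: -sign * f(t), bounds=(t_lo, t_hi), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x), float(sign * -res.fun)


def _max_abs_gap(f: Callable, fit: AffineFit, iv: Interval, grid: np.ndarray,
                 y: np.ndarray) -> tuple[float, float]:
    """Maximal |f(t) - fit(t)| on the interval with local refinement."""
    g = y - fit(grid)
    i = int(np.argmax(np.abs(g)))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    sign = 1.0 if g[i] >= 0 else -1.0
    t_star, val = _refine_extremum(lambda t: f(t) - fit(t), lo, hi, sign)
    return t_star, abs(val)


def deviation_from_additivity(delta, R: float, interval) -> DeviationResult:
    """Minimax deviation of an SR curve from the nearest affine function.

    Uses the closed form when the curve does not cross its linear
    interpolation inside the interval (constant-sign residual, e.g. concave
    or convex curves); falls back to a nested numeric minimax otherwise.
    """
    iv = _coerce_interval(interval)
    f = _as_curve(delta, R)
    grid = np.linspace(iv.t0, iv.t1, _GRID_POINTS)
    y = np.asarray([f(t) for t in grid], dtype=float) if not _vectorizable(f, grid) else f(grid)
    _check_monotone(y)

    interp = linear_interpolation(delta, R, iv)
    resid = y - interp(grid)
    inner = resid[1:-1]
    tol = 1e-13 * max(1.0, float(np.max(np.abs(y))))
    one_signed = np.all(inner >= -tol) or np.all(inner <= tol)

    if one_signed:
        t_star, X = _max_abs_gap(f, interp, iv, grid, y)
        sign = 1.0 if f(t_star) - interp(t_star) >= 0 else -1.0
        fit = AffineFit(interp.a, interp.b + sign * X / 2.0)
        return DeviationResult(fit, X / (2.0 * interp.a), t_star, "closed_form")

    return _numeric_minimax(f, grid, y, interp, iv)


def _vectorizable(f: Callable, grid: np.ndarray) -> bool:
    try:
        out = f(grid)
        return isinstance(out, np.ndarray) and out.shape == grid.shape
    except Exception:
        return False


def _numeric_minimax(f, grid, y, interp: AffineFit, iv: Interval) -> DeviationResult:
    """Nested minimax: Chebyshev-center intercept for fixed slope, bounded
    1-D search over the slope with a dense-scan fallback."""

    def psi(a: float) -> tuple[float, float]:
        r = y - a * grid
        b = (r.max() + r.min()) / 2.0
        return (r.max() - r.min()) / 2.0, b

    def objective(a: float) -> float:
        return psi(a)[0] / a

    lo, hi = interp.a / 10.0, interp.a * 10.0
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    a_star = float(res.x)
    # Guard against non-unimodal objectives: dense scan and keep the better.
    scan = np.geomspace(lo, hi, 400)
    vals = np.array([objective(a) for a in scan])
    if vals.min() < objective(a_star) - 1e-12:
        a0 = scan[int(np.argmin(vals))]
        res = minimize_scalar(objective, bounds=(a0 / 1.5, a0 * 1.5), method="bounded",
                              options={"xatol": 1e-10})
        a_star = float(res.x)
    _, b_star = psi(a_star)
    fit = AffineFit(a_star, b_star)
    t_star, X = _max_abs_gap(f, fit, iv, grid, y)
    return DeviationResult(fit, X / a_star, t_star, "numeric")


def deviation_bound(delta, R: float, interval) -> float:
    """Interpolation-error bound (t1-t0)^2 F / (16 A) on the deviation,
    with F the maximal |second derivative| on the interval.

    For the JC curve the second derivative is available in closed form and
    its |.|-maximum sits either at an endpoint or at t = ln(2)/rho.
    """
    iv = _coerce_interval(interval)
    interp = linear_interpolation(delta, R, iv)
    if isinstance(delta, SRFunction) and delta.name == "jc":
        rho = (2.0 * R - 1.0) / (R + 1.0)
        candidates = [iv.t0, iv.t1]
        if rho > 0:
            t_min2 = np.log(2.0) / rho
            if iv.t0 < t_min2 < iv.t1:
                candidates.append(t_min2)
        F = max(abs(delta_jc_derivative(R, t, 2)) for t in candidates)
    else:
        f = _as_curve(delta, R)
        grid = np.linspace(iv.t0, iv.t1, _CURVATURE_GRID)
        h = iv.width / (_CURVATURE_GRID * 4)
        d2 = np.array([(f(t + h) - 2 * f(t) + f(t - h)) / h**2
                       for t in grid[1:-1]])
        F = float(np.max(np.abs(d2)))
    return iv.width**2 * F / (16.0 * interp.a)


def _leaf_path_times(tree) -> list[float]:
    """All pairwise leaf-to-leaf path times of a dendropy tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    out = []
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            out.append(float(pdm.patristic_distance(taxa[i], taxa[j])))
    return out


def consistency_check(tree, delta, R: float) -> dict:
    """Is the SR function guaranteed consistent for this model tree?

    Computes the minimal edge time ``t_min``, the inter-leaf time range
    ``[t0, t1]`` and the deviation from additivity; the guarantee holds when
    ``dev < t_min / 2``.
    """
    leaves = [nd for nd in tree.leaf_node_iter()]
    if len(leaves) < 4:
        raise InvalidInputError("consistency is non-trivial only for >= 4 leaves")
    edge_times = [e.length for e in tree.preorder_edge_iter()
                  if e.length is not None and e.head_node.parent_node is not None]
    if not edge_times or min(edge_times) <= 0:
        raise InvalidInputError("tree must have positive edge times")
    t_min = float(min(edge_times))
    times = _leaf_path_times(tree)
    iv = Interval(min(times), max(times))
    result = deviation_from_additivity(delta, R, iv)
    verdict = "guaranteed_consistent" if result.dev < t_min / 2.0 else "not_guaranteed"
    return {
        "verdict": verdict,
        "dev": result.dev,
        "t_min": t_min,
        "t0": iv.t0,
        "t1": iv.t1,
        "margin": t_min / 2.0 - result.dev,
    }


def consistency_region(R_max: float, interval) -> float:
    """Minimal internal-edge time guaranteeing JC-distance consistency for
    every homogeneous K2P sub-model with ti-tv ratio up to ``R_max``, over
    trees whose inter-leaf times fall in the interval: twice the deviation
    from additivity at the worst ratio ``R_max``."""
    if R_max < 0.5:
        raise InvalidInputError(f"R_max must be >= 1/2, got {R_max}")
    if R_max == 0.5:
        return 0.0
    return 2.0 * deviation_from_additivity(JC, R_max, interval).dev
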