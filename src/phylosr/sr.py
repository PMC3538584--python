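"""Substitution-rate (SR) functions.

An SR function maps the per-site substitution probabilities ``(p_alpha,
p_beta)`` of an aligned pair to a scalar evolutionary distance.  Under a
homogeneous K2P sub-model with ti-tv ratio ``R``, composing an SR function
with the exact probabilities at time ``t`` turns it into a univariate
function of ``t``; an SR function is affine-additive in the sub-model iff
that univariate function is affine with positive slope.

Implemented here:

* ``delta_k2p`` -- Kimura's two-parameter distance, additive for every R
  (it recovers ``t`` exactly).
* ``delta_jc`` -- the Jukes-Cantor distance; additive only at ``R = 1/2``,
  concave in ``t`` for ``R > 1/2`` but with smaller stochastic noise.
* ``delta_tv`` -- transversion-only distance, ``beta t`` up to scale.
* ``delta_r_ml`` -- maximum-likelihood estimate of ``t`` at a known fixed R.
* ``delta_logdet`` -- LogDet distance from a 4x4 pair count matrix.

Closed forms for the time-parameterized JC distance and its first three
t-derivatives are provided for the deviation-from-additivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import InvalidInputError, InvalidParameterError, SaturationError
from .k2p import K2PParams, transition_probs

__all__ = [
    "SRFunction",
    "delta_k2p",
    "delta_jc",
    "delta_tv",
    "delta_r_ml",
    "delta_jc_time",
    "delta_jc_derivative",
    "delta_logdet",
    "delta_k2p_array",
    "delta_jc_array",
    "delta_tv_array",
    "get_sr_function",
    "JC",
    "K2P",
    "TV",
]


def _unpack(probs) -> tuple[float, float]:
    if hasattr(probs, "p_alpha"):
        return probs.p_alpha, probs.p_beta
    if hasattr(probs, "p_alpha_hat"):
        return probs.p_alpha_hat, probs.p_beta_hat
    pa, pb = probs
    return pa, pb


def delta_k2p(probs) -> float:
    """Kimura's distance -1/2 ln(1-2p_b-2p_a) - 1/4 ln(1-4p_b).

    On exact model probabilities this equals ``alpha t + 2 beta t = t``.
    """
    pa, pb = _unpack(probs)
    w = 1.0 - 2.0 * pb - 2.0 * pa
    v = 1.0 - 4.0 * pb
    if w <= 0:
        raise SaturationError(
            f"1 - 2p_beta - 2p_alpha = {w:g} <= 0", bound="1-2p_beta-2p_alpha"
        )
    if v <= 0:
        raise SaturationError(f"1 - 4p_beta = {v:g} <= 0", bound="1-4p_beta")
    return float(-0.5 * np.log(w) - 0.25 * np.log(v))


def delta_jc(probs) -> float:
    """Jukes-Cantor distance -3/4 ln(1 - 4/3 (p_a + 2 p_b))."""
    pa, pb = _unpack(probs)
    p = pa + 2.0 * pb
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        raise SaturationError(f"1 - 4/3 (p_alpha + 2p_beta) = {arg:g} <= 0", bound="p<3/4")
    return float(-0.75 * np.log(arg))


def delta_tv(probs) -> float:
    """Transversion-only distance -1/4 ln(1-4p_b); equals ``beta t`` exactly."""
    _, pb = _unpack(probs)
    v = 1.0 - 4.0 * pb
    if v <= 0:
        raise SaturationError(f"1 - 4p_beta = {v:g} <= 0", bound="1-4p_beta")
    return float(-0.25 * np.log(v))


# Vectorized variants used by the experiment drivers: saturated entries are
# returned as NaN so the caller can apply its cap policy in bulk.

def delta_k2p_array(pa, pb):
    w = 1.0 - 2.0 * pb - 2.0 * pa
    v = 1.0 - 4.0 * pb
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((w > 0) & (v > 0), -0.5 * np.log(np.where(w > 0, w, 1.0))
                       - 0.25 * np.log(np.where(v > 0, v, 1.0)), np.nan)
    return out


def delta_jc_array(pa, pb):
    arg = 1.0 - (pa + 2.0 * pb) * 4.0 / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(arg > 0, -0.75 * np.log(np.where(arg > 0, arg, 1.0)), np.nan)


def delta_tv_array(pa, pb):
    v = 1.0 - 4.0 * pb
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(v > 0, -0.25 * np.log(np.where(v > 0, v, 1.0)), np.nan)


_T_MAX = 20.0


def delta_r_ml(est, R: float) -> float:
    """ML estimate of the time t at a known ti-tv ratio R.

    Maximizes the trinomial log-likelihood

        n_ti ln p_alpha(t) + n_tv ln(2 p_beta(t)) + n_same ln(1 - p_alpha(t) - 2 p_beta(t))

    over ``t in (0, 20]`` with ``p_alpha, p_beta`` the exact K2P(R)
    probabilities.  On observations lying exactly on the model curve for this
    R it returns the Kimura distance (the exact ``t``).  The maximizer does
    not depend on the sequence length, only on the observed proportions.
    """
    if R < 0.5:
        raise InvalidParameterError(f"ti-tv ratio R must be >= 1/2, got {R}")
    pa_hat, pb_hat = _unpack(est)
    if pa_hat == 0.0 and pb_hat == 0.0:
        return 0.0

    def neg_loglik(t: float) -> float:
        p = transition_probs(K2PParams(R, t))
        same = 1.0 - p.p_alpha - 2.0 * p.p_beta
        ll = 0.0
        if pa_hat > 0:
            ll += pa_hat * np.log(p.p_alpha)
        if pb_hat > 0:
            ll += 2.0 * pb_hat * np.log(2.0 * p.p_beta)
        frac_same = 1.0 - pa_hat - 2.0 * pb_hat
        if frac_same > 0:
            ll += frac_same * np.log(same)
        return -ll

    res = minimize_scalar(neg_loglik, bounds=(1e-8, _T_MAX), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:
        from .errors import NumericalError

        raise NumericalError("ML time estimate did not converge",
                             {"R": R, "pa": pa_hat, "pb": pb_hat, "result": res})
    return float(res.x)


def _rho(R: float) -> float:
    return (2.0 * R - 1.0) / (R + 1.0)


def delta_jc_time(R: float, t) -> float | np.ndarray:
    """JC distance as a function of time under K2P(R):

        3 t / (2 (R+1)) - 3/4 ln((1 + 2 e^{-rho t}) / 3),   rho = (2R-1)/(R+1).

    Equals ``delta_jc(transition_probs(R, t))``; reduces to ``t`` at R = 1/2.
    """
    if R < 0.5:
        raise InvalidParameterError(f"ti-tv ratio R must be >= 1/2, got {R}")
    t = np.asarray(t, dtype=float)
    rho = _rho(R)
    val = 1.5 * t / (R + 1.0) - 0.75 * np.log((1.0 + 2.0 * np.exp(-rho * t)) / 3.0)
    return float(val) if val.ndim == 0 else val


def delta_jc_derivative(R: float, t, order: int = 1):
    """First, second, or third t-derivative of the time-parameterized JC
    distance, in closed form.

    For R > 1/2 the first derivative is positive and the second negative
    (the function is concave increasing); the second derivative attains its
    global minimum -(3/16) rho^2 at t = ln(2)/rho.
    """
    if order not in (1, 2, 3):
        raise InvalidInputError(f"derivative order must be 1, 2 or 3, got {order}")
    if R < 0.5:
        raise InvalidParameterError(f"ti-tv ratio R must be >= 1/2, got {R}")
    t = np.asarray(t, dtype=float)
    rho = _rho(R)
    e = np.exp(-rho * t)
    if order == 1:
        val = 1.5 / (R + 1.0) + 1.5 * rho * e / (1.0 + 2.0 * e)
    elif order == 2:
        val = -1.5 * rho**2 * e / (1.0 + 2.0 * e) ** 2
    else:
        val = 1.5 * rho**3 * (1.0 - 2.0 * e) * e / (1.0 + 2.0 * e) ** 3
    return float(val) if val.ndim == 0 else val


def delta_logdet(joint_counts) -> float:
    """LogDet distance from a 4x4 joint pair-count matrix.

    Computes ``-1/4 ln det(F_hat)`` with ``F_hat`` the row-normalized joint
    frequency matrix.  Additive under general time-reversible divergence;
    raises on non-positive determinant (saturation).
    """
    C = np.asarray(joint_counts, dtype=float)
    if C.shape != (4, 4) or np.any(C < 0) or C.sum() <= 0:
        raise InvalidInputError("joint_counts must be a non-negative 4x4 matrix")
    F = C / C.sum()
    rows = F.sum(axis=1)
    if np.any(rows <= 0):
        raise SaturationError("a row of the divergence matrix is empty", bound="det>0")
    F_hat = F / rows[:, None]
    det = np.linalg.det(F_hat)
    if det <= 0:
        raise SaturationError(f"det(F_hat) = {det:g} <= 0", bound="det>0")
    return float(-0.25 * np.log(det))


@dataclass(frozen=True)
class SRFunction:
    """A named SR function with both probability- and time-domain views.

    ``from_probs`` maps a :class:`~phylosr.k2p.TransitionProbs` (or estimate)
    to a distance; ``from_time(R, t)`` is its composition with the exact K2P
    probabilities; ``from_probs_array(pa, pb)`` is the vectorized variant
    returning NaN on saturation.  ``sigma(R, t, k)`` is the delta-method
    standard deviation of the estimator when available.
    """

    name: str
    from_probs: Callable
    from_probs_array: Callable
    additive_in_k2p: bool
    _from_time: Callable | None = None
    _sigma: Callable | None = None

    def from_time(self, R: float, t):
        if self._from_time is not None:
            return self._from_time(R, t)
        tt = np.asarray(t, dtype=float)
        if tt.ndim == 0:
            p = transition_probs(K2PParams(R, float(tt)))
            return self.from_probs(p)
        return np.array([self.from_time(R, float(x)) for x in tt])

    def sigma(self, R: float, t: float, k: int) -> float:
        if self._sigma is None:
            raise InvalidInputError(f"no analytic noise formula for SR function {self.name!r}")
        return self._sigma(R, t, k)

    def __call__(self, probs) -> float:
        return self.from_probs(probs)


def _sigma_jc(R, t, k):
    from .noise import sigma_jc

    return sigma_jc(R, t, k).sd


def _sigma_k2p(R, t, k):
    from .noise import sigma_k2p

    return sigma_k2p(R, t, k).sd


JC = SRFunction("jc", delta_jc, delta_jc_array, additive_in_k2p=False,
                _from_time=delta_jc_time, _sigma=_sigma_jc)
K2P = SRFunction("k2p", delta_k2p, delta_k2p_array, additive_in_k2p=True,
                 _from_time=lambda R, t: np.asarray(t, dtype=float) * 1.0,
                 _sigma=_sigma_k2p)
TV = SRFunction("tv", delta_tv, delta_tv_array, additive_in_k2p=True,
                _from_time=lambda R, t: np.asarray(t, dtype=float) / (2.0 * (R + 1.0)))


def _make_r_ml(R_fixed: float) -> SRFunction:
    def from_probs(probs):
        return delta_r_ml(probs, R_fixed)

    def from_probs_array(pa, pb):
        pa = np.asarray(pa, dtype=float)
        pb = np.asarray(pb, dtype=float)
        flat = np.empty(pa.size)
        for i, (x, y) in enumerate(zip(pa.ravel(), pb.ravel())):
            try:
                flat[i] = delta_r_ml((x, y), R_fixed)
            except Exception:
                flat[i] = np.nan
        return flat.reshape(pa.shape)

    # No closed time form: the generic path composes from_probs with the
    # exact probabilities, which is correct even when the generating R
    # differs from R_fixed.
    return SRFunction(f"r-ml:{R_fixed:g}", from_probs, from_probs_array,
                      additive_in_k2p=True)


def get_sr_function(name: str) -> SRFunction:
    """Resolve an SR function by name: ``jc``, ``k2p``, ``tv``, ``r-ml:<R>``."""
    key = name.strip().lower()
    if key == "jc":
        return JC
    if key == "k2p":
        return K2P
    if key == "tv":
        return TV
    if key.startswith("r-ml:"):
        return _make_r_ml(float(key.split(":", 1)[1]))
    raise InvalidInputError(f"unknown SR function {name!r}")
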