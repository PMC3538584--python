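"""First-order (delta-method) noise of the SR distance estimators.

The per-site mismatch counts of an aligned pair of length ``k`` are
trinomial: a site shows a transition-type difference with probability
``p_alpha``, a transversion-type difference with probability ``2 p_beta``,
and no difference otherwise.  Propagating the multinomial covariance of the
estimates ``(p_alpha_hat, p_beta_hat)`` through a distance formula gives its
first-order variance; both analytic formulas here scale exactly as ``1/k``.

For the Kimura distance ``f(p_a, p_b) = -1/2 ln w - 1/4 ln v`` with
``w = 1 - 2 p_a - 2 p_b`` and ``v = 1 - 4 p_b``,

    df/dp_a = 1/w,           df/dp_b = 1/w + 1/v,
    Var = [ (df/dp_a)^2 p_a (1 - p_a) + (df/dp_b)^2 p_b (1 - 2 p_b) / 2
            - 2 (df/dp_a)(df/dp_b) p_a p_b ] / k .

For the Jukes-Cantor distance, which depends only on the total mismatch
probability ``p = p_a + 2 p_b`` (binomial),

    Var = p (1 - p) / ( k (1 - 4p/3)^2 ) .

The JC estimator tracks a single binomial proportion and is strictly less
noisy than the Kimura estimator whenever R > 1/2; this reduced stochastic
noise is what can compensate for its systematic bias (deviation from
additivity) under transition-transversion-biased models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .k2p import K2PParams, pair_mismatch_counts, _evolve

__all__ = ["NoiseEstimate", "sigma_k2p", "sigma_jc", "sigma_affine",
           "empirical_sigma", "var_k2p", "var_jc"]


@dataclass(frozen=True)
class NoiseEstimate:
    """Standard deviation of an SR distance estimator (rate units)."""

    sd: float
    k: int
    source: str  # "analytic" | "monte_carlo"
    n_saturated: int = 0
    warning: str | None = None


def var_k2p(R, t, k):
    """Delta-method variance of the Kimura distance; array-safe in t."""
    t = np.asarray(t, dtype=float)
    p = K2PParams(float(R), 0.0)  # validates R
    a, b = p.alpha, p.beta
    pa = (1.0 + np.exp(-4.0 * b * t) - 2.0 * np.exp(-2.0 * (a + b) * t)) / 4.0
    pb = (1.0 - np.exp(-4.0 * b * t)) / 4.0
    w = 1.0 - 2.0 * pa - 2.0 * pb
    v = 1.0 - 4.0 * pb
    fa = 1.0 / w
    fb = 1.0 / w + 1.0 / v
    var = (fa**2 * pa * (1.0 - pa) + fb**2 * pb * (1.0 - 2.0 * pb) / 2.0
           - 2.0 * fa * fb * pa * pb) / k
    return float(var) if var.ndim == 0 else var


def var_jc(R, t, k):
    """Delta-method variance of the JC distance; array-safe in t."""
    if R < 0.5:
        raise InvalidParameterError(f"ti-tv ratio R must be >= 1/2, got {R}")
    t = np.asarray(t, dtype=float)
    p = 0.75 - 0.25 * np.exp(-2.0 * t / (R + 1.0)) - 0.5 * np.exp(-(2.0 * R + 1.0) * t / (R + 1.0))
    var = p * (1.0 - p) / (k * (1.0 - 4.0 * p / 3.0) ** 2)
    return float(var) if var.ndim == 0 else var


def sigma_k2p(R: float, t: float, k: int) -> NoiseEstimate:
    """Delta-method SD of the Kimura distance estimator."""
    if k < 1:
        raise InvalidInputError(f"sequence length k must be >= 1, got {k}")
    return NoiseEstimate(float(np.sqrt(var_k2p(R, t, k))), k, "analytic")


def sigma_jc(R: float, t: float, k: int) -> NoiseEstimate:
    """Delta-method SD of the JC distance estimator."""
    if k < 1:
        raise InvalidInputError(f"sequence length k must be >= 1, got {k}")
    return NoiseEstimate(float(np.sqrt(var_jc(R, t, k))), k, "analytic")


def sigma_affine(fit, sd_k2p: NoiseEstimate) -> NoiseEstimate:
    """Noise of an affine-additive surrogate a*t + b: the Kimura-estimator
    SD scaled by the slope a (the intercept adds no noise)."""
    if fit.a <= 0:
        raise InvalidInputError("affine fit must have positive slope")
    return NoiseEstimate(fit.a * sd_k2p.sd, sd_k2p.k, sd_k2p.source)


def empirical_sigma(delta, R: float, t: float, k: int, reps: int,
                    seed: int | None = None) -> NoiseEstimate:
    """Monte-Carlo SD of an SR distance over simulated two-leaf alignments.

    Simulates ``reps`` independent pairs of ``k``-site sequences separated by
    total time ``t``, applies the SR function to the empirical mismatch
    proportions, and returns the sample SD.  Saturated replicates are dropped
    (capping them would bias the SD) and counted; a warning is attached when
    more than 10% saturate.
    """
    if reps < 100:
        raise InvalidInputError(f"reps must be >= 100, got {reps}")
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, size=(reps, k), dtype=np.int8)
    other = _evolve(root, R, t, rng)
    n_ti, n_tv = pair_mismatch_counts(root, other)
    pa = n_ti / k
    pb = n_tv / (2.0 * k)
    vals = delta.from_probs_array(pa, pb)
    ok = np.isfinite(vals)
    n_sat = int(reps - ok.sum())
    if ok.sum() < 2:
        raise InvalidInputError("all replicates saturated; cannot estimate SD")
    sd = float(np.std(vals[ok], ddof=1))
    warning = None
    if n_sat > 0.10 * reps:
        warning = (f"{n_sat}/{reps} replicates saturated; "
                   "SD over the remainder may be unreliable")
    return NoiseEstimate(sd, k, "monte_carlo", n_saturated=n_sat, warning=warning)
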