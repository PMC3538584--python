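"""Quartet resolution: four-point method, Fisher-criterion prediction,
and Monte-Carlo accuracy.

Two prototype quartets with true split (12|34), internal edge time ``t_i``,
two short external edges ``t_s`` and two long ones ``t_l``:

* type A ("Farris zone"): both short edges on one side of the split, both
  long ones on the other.  A concave SR function *increases* the four-point
  separation here, helping reconstruction.
* type B ("Felsenstein zone"): a short and a long edge on each side.  The
  pair times ``d12 = d34`` sit near the middle of the interpolation interval
  ``[d13, d24]``, so concavity *shrinks* the separation by about twice the
  deviation from additivity; when the deviation exceeds ``t_i / 2`` the wrong
  split (13|24) wins even on exact distances.

The Fisher criterion FC = |mu1 - mu2| / sqrt(sigma1^2 + sigma2^2) scores the
separation between the two competing pair-time sums under an SR function,
using exact expected distances for the means and the sum of the two
delta-method variances for each sum's variance (covariance from shared edges
is deliberately ignored).  Comparing FC between two SR functions factors into
a SEP ratio (systematic separation) over a NOISE ratio (stochastic error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .k2p import _evolve, pair_mismatch_counts
from .sr import SRFunction

__all__ = [
    "SPLITS",
    "QuartetModel",
    "FCResult",
    "exact_distances",
    "four_point_method",
    "fisher_criterion",
    "sep_noise_ratios",
    "quartet_accuracy_sim",
    "quartet_accuracy_multi",
]

SPLITS = ("12|34", "13|24", "14|23")
# pair indices (0-based leaves) contributing to each split sum
_SPLIT_PAIRS = {
    "12|34": ((0, 1), (2, 3)),
    "13|24": ((0, 2), (1, 3)),
    "14|23": ((0, 3), (1, 2)),
}


@dataclass(frozen=True)
class QuartetModel:
    """A four-leaf model tree of type A or B with true split (12|34)."""

    qtype: str  # "A" | "B"
    t_i: float
    t_s: float
    t_l: float
    R: float

    def __post_init__(self):
        if self.qtype not in ("A", "B"):
            raise InvalidInputError(f"quartet type must be 'A' or 'B', got {self.qtype!r}")
        if min(self.t_i, self.t_s, self.t_l) <= 0:
            raise InvalidInputError("all quartet edge times must be positive")
        if self.t_s > self.t_l:
            raise InvalidInputError("require t_s <= t_l")

    def external_times(self) -> tuple[float, float, float, float]:
        """Edge times of leaves 1..4; leaves 1,2 hang off one end of the
        internal edge and leaves 3,4 off the other."""
        if self.qtype == "A":
            return self.t_s, self.t_s, self.t_l, self.t_l
        return self.t_s, self.t_l, self.t_s, self.t_l


@dataclass(frozen=True)
class FCResult:
    """Fisher-criterion separation between two competing split sums."""

    sep: float
    noise: float
    fc: float
    split_pair: tuple[str, str]


def exact_distances(q: QuartetModel) -> np.ndarray:
    """4x4 matrix of exact leaf-pair path times."""
    e = q.external_times()
    D = np.zeros((4, 4))
    for i in range(4):
        for j in range(i + 1, 4):
            same_side = (i < 2) == (j < 2)
            D[i, j] = D[j, i] = e[i] + e[j] + (0.0 if same_side else q.t_i)
    return D


def _split_sums(D: np.ndarray) -> np.ndarray:
    return np.array([
        D[..., 0, 1] + D[..., 2, 3],
        D[..., 0, 2] + D[..., 1, 3],
        D[..., 0, 3] + D[..., 1, 2],
    ])


def four_point_method(D, tie_seed: int | None = None) -> str:
    """Resolve a quartet by the minimal of the three pair-distance sums.

    ``D`` is a 4x4 matrix (or object with a ``matrix`` attribute) of the six
    pairwise distances; leaves are ordered 1..4.  Exact ties are broken
    uniformly at random with ``tie_seed``.
    """
    M = np.asarray(getattr(D, "matrix", D), dtype=float)
    if M.shape != (4, 4) or not np.all(np.isfinite(M[np.triu_indices(4, 1)])):
        raise InvalidInputError("four_point_method needs six finite distances on 4 leaves")
    sums = _split_sums(M)
    winners = np.flatnonzero(sums == sums.min())
    if len(winners) == 1:
        return SPLITS[winners[0]]
    rng = np.random.default_rng(tie_seed)
    return SPLITS[rng.choice(winners)]


def _sum_stats(q: QuartetModel, delta: SRFunction, k: int, split: str) -> tuple[float, float]:
    """(mean, variance) of a split's distance sum under the SR function."""
    D = exact_distances(q)
    (i1, j1), (i2, j2) = _SPLIT_PAIRS[split]
    t_a, t_b = D[i1, j1], D[i2, j2]
    mu = float(delta.from_time(q.R, t_a)) + float(delta.from_time(q.R, t_b))
    var = delta.sigma(q.R, t_a, k) ** 2 + delta.sigma(q.R, t_b, k) ** 2
    return mu, var


def fisher_criterion(q: QuartetModel, delta: SRFunction, k: int,
                     alt_split: str = "13|24") -> FCResult:
    """FC between the true-split sum (12|34) and a competing split sum."""
    if alt_split not in SPLITS or alt_split == "12|34":
        raise InvalidInputError(f"alt_split must be '13|24' or '14|23', got {alt_split!r}")
    mu1, var1 = _sum_stats(q, delta, k, "12|34")
    mu2, var2 = _sum_stats(q, delta, k, alt_split)
    sep = abs(mu1 - mu2)
    noise = float(np.sqrt(var1 + var2))
    return FCResult(sep, noise, sep / noise, ("12|34", alt_split))


def sep_noise_ratios(q: QuartetModel, delta1: SRFunction, delta2: SRFunction,
                     k: int) -> tuple[float, float, float]:
    """(SEP ratio, NOISE ratio, FC ratio) of two SR functions for the
    (12|34)-vs-(13|24) comparison; FC ratio = SEP ratio / NOISE ratio."""
    r1 = fisher_criterion(q, delta1, k)
    r2 = fisher_criterion(q, delta2, k)
    sep_ratio = r1.sep / r2.sep
    noise_ratio = r1.noise / r2.noise
    return sep_ratio, noise_ratio, sep_ratio / noise_ratio


def apply_cap(dists: np.ndarray, default_cap: float = 5.0) -> tuple[np.ndarray, int]:
    """Replace saturated (NaN) entries by 2x the largest finite distance in
    the same replicate's matrix, or ``default_cap`` if none is finite.

    ``dists`` has shape (..., n_pairs); returns (capped array, event count).
    """
    sat = ~np.isfinite(dists)
    n_events = int(sat.sum())
    if n_events == 0:
        return dists, 0
    with np.errstate(all="ignore"):
        row_max = np.nanmax(np.where(sat, -np.inf, dists), axis=-1)
    row_max = np.where(np.isfinite(row_max), row_max, default_cap / 2.0)
    cap = 2.0 * row_max
    out = np.where(sat, cap[..., None], dists)
    return out, n_events


_PAIRS = [(0, 1), (2, 3), (0, 2), (1, 3), (0, 3), (1, 2)]


def simulate_quartet_pair_stats(q: QuartetModel, k: int, reps: int,
                                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Empirical (p_alpha_hat, p_beta_hat) for the six leaf pairs over
    ``reps`` simulated alignments; arrays of shape (reps, 6) ordered
    (12, 34, 13, 24, 14, 23)."""
    e = q.external_times()
    root = rng.integers(0, 4, size=(reps, k), dtype=np.int8)
    mid = _evolve(root, q.R, q.t_i, rng)
    leaves = [
        _evolve(root, q.R, e[0], rng),
        _evolve(root, q.R, e[1], rng),
        _evolve(mid, q.R, e[2], rng),
        _evolve(mid, q.R, e[3], rng),
    ]
    pa = np.empty((reps, 6))
    pb = np.empty((reps, 6))
    for idx, (i, j) in enumerate(_PAIRS):
        n_ti, n_tv = pair_mismatch_counts(leaves[i], leaves[j])
        pa[:, idx] = n_ti / k
        pb[:, idx] = n_tv / (2.0 * k)
    return pa, pb


def quartet_accuracy_multi(q: QuartetModel, deltas: list[SRFunction], k: int,
                           reps: int, seed: int | None = None,
                           batch: int = 10_000) -> dict[str, float]:
    """Four-point accuracy of several SR functions on the *same* simulated
    replicates (a paired design: the accuracy difference between two SR
    functions is then estimated with far smaller variance than from
    independent runs).  Simulation is batched to bound memory.
    """
    if reps < 1:
        raise InvalidInputError(f"reps must be >= 1, got {reps}")
    rng = np.random.default_rng(seed)
    correct = {d.name: 0 for d in deltas}
    done = 0
    while done < reps:
        b = min(batch, reps - done)
        pa, pb = simulate_quartet_pair_stats(q, k, b, rng)
        tie_noise = rng.random((b, 3))  # shared across SR functions
        for d in deltas:
            dists, _ = apply_cap(d.from_probs_array(pa, pb))
            sums = np.stack([dists[:, 0] + dists[:, 1],
                             dists[:, 2] + dists[:, 3],
                             dists[:, 4] + dists[:, 5]], axis=1)
            is_min = sums == sums.min(axis=1, keepdims=True)
            keyed = np.where(is_min, tie_noise, np.inf)
            correct[d.name] += int(np.sum(np.argmin(keyed, axis=1) == 0))
        done += b
    return {name: c / reps for name, c in correct.items()}


def quartet_accuracy_sim(q: QuartetModel, delta: SRFunction, k: int, reps: int,
                         seed: int | None = None,
                         return_detail: bool = False):
    """Monte-Carlo probability that the four-point method on estimated
    SR distances recovers the true split (12|34).

    Saturated distances are capped (see :func:`apply_cap`); exact ties among
    the three split sums are broken uniformly at random.
    """
    if reps < 1:
        raise InvalidInputError(f"reps must be >= 1, got {reps}")
    rng = np.random.default_rng(seed)
    pa, pb = simulate_quartet_pair_stats(q, k, reps, rng)
    dists = delta.from_probs_array(pa, pb)
    dists, n_sat = apply_cap(dists)
    sums = np.stack([dists[:, 0] + dists[:, 1],
                     dists[:, 2] + dists[:, 3],
                     dists[:, 4] + dists[:, 5]], axis=1)
    min_val = sums.min(axis=1, keepdims=True)
    is_min = sums == min_val
    n_min = is_min.sum(axis=1)
    # tie-break: uniform random pick among the minimizing splits
    keyed = np.where(is_min, rng.random(sums.shape), np.inf)
    pick = np.argmin(keyed, axis=1)
    correct = pick == 0
    acc = float(np.mean(correct))
    if return_detail:
        return {
            "accuracy": acc,
            "n_saturated_entries": n_sat,
            "tie_fraction": float(np.mean(n_min > 1)),
            "reps": reps,
        }
    return acc
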