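"""Kimura two-parameter (K2P) substitution model.

The homogeneous K2P process is parameterized by a transition-transversion
(ti-tv) ratio ``R = alpha / (2 beta) >= 1/2`` and an evolutionary time ``t``.
The unit rate matrix is normalized so that ``alpha + 2 beta = 1`` (one
expected substitution per site per unit time), giving

    alpha = R / (R + 1),      beta = 1 / (2 (R + 1)).

Transitions are A<->G and C<->T; the four remaining unordered pairs are
transversions.  This module provides the exact per-site substitution
probabilities ``(p_alpha, p_beta)`` at time ``t``, their inversion back to
``(alpha t, beta t)``, a site-i.i.d. sequence simulator along trees, and the
empirical estimator of ``(p_alpha, p_beta)`` from an aligned sequence pair.

Convention: ``p_beta`` is the probability of *each* of the two transversion
targets, so the empirical analogue divides the transversion-difference count
by ``2k``.  Many texts instead use the total transversion proportion
``Q = 2 p_beta``; all formulas in this package follow the per-target
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError, SaturationError

__all__ = [
    "NUCLEOTIDES",
    "K2PParams",
    "TransitionProbs",
    "TransitionProbEstimate",
    "Alignment",
    "unit_rate_matrix",
    "transition_probs",
    "invert_transition_probs",
    "transition_matrix",
    "simulate_alignment",
    "simulate_site_patterns",
    "estimate_pair_stats",
    "pair_mismatch_counts",
]

# Integer coding: A=0, G=1, C=2, T=3.  XOR tricks below rely on this order:
# b ^ 1 is the transition partner of b, and b ^ 2, b ^ 3 are its two
# transversion targets.
NUCLEOTIDES = "AGCT"
_CODE = {c: i for i, c in enumerate(NUCLEOTIDES)}


@dataclass(frozen=True)
class K2PParams:
    """A point (R, t) in the homogeneous K2P model.

    Parameters
    ----------
    R : float
        ti-tv ratio, ``R = alpha / (2 beta) >= 1/2``.  ``R = 1/2`` is the
        Jukes-Cantor sub-model (``alpha = beta``).
    t : float
        Evolutionary time in expected substitutions per site (>= 0).
    """

    R: float
    t: float
    alpha: float = field(init=False)
    beta: float = field(init=False)

    def __post_init__(self):
        if self.R < 0.5:
            raise InvalidParameterError(f"ti-tv ratio R must be >= 1/2, got {self.R}")
        if self.t < 0:
            raise InvalidParameterError(f"time t must be >= 0, got {self.t}")
        object.__setattr__(self, "alpha", self.R / (self.R + 1.0))
        object.__setattr__(self, "beta", 1.0 / (2.0 * (self.R + 1.0)))


@dataclass(frozen=True)
class TransitionProbs:
    """Exact per-site substitution probabilities (p_alpha, p_beta).

    ``p_alpha`` is the probability of a transition-type difference,
    ``p_beta`` the probability of each transversion-type difference.
    """

    p_alpha: float
    p_beta: float


@dataclass(frozen=True)
class TransitionProbEstimate:
    """Empirical (p_alpha, p_beta) from an aligned pair of k sites.

    Unlike exact model probabilities, estimates may violate the model-domain
    bounds (saturation), in which case downstream distance formulas raise
    :class:`~phylosr.errors.SaturationError`.
    """

    p_alpha_hat: float
    p_beta_hat: float
    k: int


@dataclass
class Alignment:
    """A gap-free multiple sequence alignment over {A, C, G, T}."""

    labels: list[str]
    sequences: list[str]

    def __post_init__(self):
        if len(self.labels) != len(self.sequences):
            raise InvalidInputError("labels and sequences differ in number")
        if len(set(self.labels)) != len(self.labels):
            raise InvalidInputError("duplicate leaf labels in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise InvalidInputError("sequences have unequal lengths")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def sequence(self, label: str) -> str:
        return self.sequences[self.labels.index(label)]

    def to_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(s), id=lab, description="")
            for lab, s in zip(self.labels, self.sequences)
        ]
        seqio_write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio.SeqIO import parse as seqio_parse

        labels, seqs = [], []
        for rec in seqio_parse(str(path), "fasta"):
            labels.append(rec.id)
            seqs.append(str(rec.seq).upper())
        if not labels:
            raise InvalidInputError(f"no sequences found in {path}")
        return cls(labels, seqs)


def unit_rate_matrix(R: float) -> np.ndarray:
    """K2P unit rate matrix (rows/cols ordered A, G, C, T).

    Off-diagonal entries equal ``beta`` except the transition pairs
    (A<->G, C<->T), which equal ``alpha``; rows sum to zero and
    ``alpha + 2 beta = 1``.
    """
    if R < 0.5:
        raise InvalidParameterError(f"ti-tv ratio R must be >= 1/2, got {R}")
    alpha = R / (R + 1.0)
    beta = 1.0 / (2.0 * (R + 1.0))
    Q = np.full((4, 4), beta)
    for b in range(4):
        Q[b, b ^ 1] = alpha
        Q[b, b] = -(alpha + 2 * beta)
    return Q


def transition_probs(params: K2PParams) -> TransitionProbs:
    """Exact (p_alpha, p_beta) at (R, t).

    p_alpha = (1 + e^{-4 beta t} - 2 e^{-2 alpha t - 2 beta t}) / 4
    p_beta  = (1 - e^{-4 beta t}) / 4
    """
    a, b, t = params.alpha, params.beta, params.t
    p_alpha = (1.0 + np.exp(-4.0 * b * t) - 2.0 * np.exp(-2.0 * (a + b) * t)) / 4.0
    p_beta = (1.0 - np.exp(-4.0 * b * t)) / 4.0
    return TransitionProbs(float(p_alpha), float(p_beta))


def invert_transition_probs(probs) -> tuple[float, float]:
    """Invert (p_alpha, p_beta) to (alpha*t, beta*t).

    Raises :class:`SaturationError` when either log argument is <= 0.
    """
    pa, pb = probs.p_alpha if hasattr(probs, "p_alpha") else probs[0], (
        probs.p_beta if hasattr(probs, "p_beta") else probs[1]
    )
    w = 1.0 - 2.0 * pb - 2.0 * pa
    v = 1.0 - 4.0 * pb
    if w <= 0:
        raise SaturationError(
            f"1 - 2*p_beta - 2*p_alpha = {w:g} <= 0", bound="1-2p_beta-2p_alpha"
        )
    if v <= 0:
        raise SaturationError(f"1 - 4*p_beta = {v:g} <= 0", bound="1-4p_beta")
    alpha_t = -0.5 * np.log(w) + 0.25 * np.log(v)
    beta_t = -0.25 * np.log(v)
    return float(alpha_t), float(beta_t)


def transition_matrix(R: float, t: float) -> np.ndarray:
    """Stochastic transition matrix e^{t Q(R)} in closed form."""
    p = transition_probs(K2PParams(R, t))
    P = np.full((4, 4), p.p_beta)
    for b in range(4):
        P[b, b ^ 1] = p.p_alpha
        P[b, b] = 1.0 - p.p_alpha - 2.0 * p.p_beta
    return P


def _mutation_thresholds(R: float, t: float) -> tuple[float, float, float]:
    """Cumulative probabilities of the XOR mutation classes (same, ti, tv)."""
    p = transition_probs(K2PParams(R, t))
    same = 1.0 - p.p_alpha - 2.0 * p.p_beta
    return same, same + p.p_alpha, same + p.p_alpha + p.p_beta


def _evolve(parent: np.ndarray, R: float, t: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve coded sequences (any shape) along one edge of time t."""
    c1, c2, c3 = _mutation_thresholds(R, t)
    u = rng.random(parent.shape)
    # XOR mask: 0 same, 1 transition, 2/3 the two transversions
    mask = (u >= c1).astype(np.int8) + (u >= c2).astype(np.int8) + (u >= c3).astype(np.int8)
    return parent ^ mask


def _tree_edges(tree) -> tuple[object, list[tuple[object, object, float]]]:
    """Root node and (parent, child, length) list in preorder for a dendropy tree."""
    edges = []
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            el = node.edge.length if node.edge.length is not None else 0.0
            if el < 0:
                raise InvalidInputError(f"negative edge length {el}")
            edges.append((node.parent_node, node, float(el)))
    return tree.seed_node, edges


def simulate_site_patterns(
    tree, R: float, k: int, n_reps: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Simulate coded leaf sequences for ``n_reps`` independent replicates.

    Returns a mapping leaf-label -> int8 array of shape (n_reps, k).  The
    root sequence is i.i.d. uniform over the four nucleotides; each edge
    applies the K2P transition matrix for its time length independently per
    site.  The model is time-reversible with uniform stationary distribution,
    so the leaf joint law does not depend on the root placement.
    """
    if k < 1:
        raise InvalidInputError(f"sequence length k must be >= 1, got {k}")
    root, edges = _tree_edges(tree)
    states = {id(root): rng.integers(0, 4, size=(n_reps, k), dtype=np.int8)}
    leaves: dict[str, np.ndarray] = {}
    if root.is_leaf():
        leaves[root.taxon.label] = states[id(root)]
    for parent, child, el in edges:
        seq = _evolve(states[id(parent)], R, el, rng)
        if child.is_leaf():
            leaves[child.taxon.label] = seq
        else:
            states[id(child)] = seq
    return leaves


def simulate_alignment(tree, R: float, k: int, seed: int | None = None) -> Alignment:
    """Simulate one alignment of ``k`` sites along ``tree`` under K2P(R).

    ``tree`` is a dendropy tree with edge lengths in time units.  Identical
    seeds give identical output.
    """
    rng = np.random.default_rng(seed)
    leaves = simulate_site_patterns(tree, R, k, 1, rng)
    labels = sorted(leaves)
    seqs = ["".join(NUCLEOTIDES[b] for b in leaves[lab][0]) for lab in labels]
    return Alignment(labels, seqs)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise InvalidInputError(f"invalid nucleotide symbol {exc.args[0]!r}") from None


def pair_mismatch_counts(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Transition- and transversion-difference counts along the last axis.

    Works on coded arrays of any matching shape (replicates x sites)."""
    x = a ^ b
    n_ti = np.sum(x == 1, axis=-1)
    n_tv = np.sum(x >= 2, axis=-1)
    return n_ti, n_tv


def estimate_pair_stats(seq_i: str, seq_j: str) -> TransitionProbEstimate:
    """Empirical (p_alpha, p_beta) for an aligned pair.

    ``p_alpha_hat = n_ti / k`` and ``p_beta_hat = n_tv / (2k)`` (per-target
    transversion convention; see module docstring).
    """
    if len(seq_i) != len(seq_j):
        raise InvalidInputError("aligned sequences must have equal length")
    if len(seq_i) == 0:
        raise InvalidInputError("empty sequences")
    a, b = _encode(seq_i), _encode(seq_j)
    n_ti, n_tv = pair_mismatch_counts(a, b)
    k = len(seq_i)
    return TransitionProbEstimate(float(n_ti) / k, float(n_tv) / (2 * k), k)
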