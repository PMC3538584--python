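"""Trees, distance matrices, neighbor joining, and Robinson-Foulds.

Trees are dendropy objects throughout the public API (Newick I/O, edge
lengths in time units, unrooted interpretation).  Neighbor joining is
implemented in-repo so its contracts -- affine invariance of the topology
and deterministic smallest-index tie-breaking -- are testable; it returns
negative branch lengths unchanged since evaluation is topology-only.

Robinson-Foulds distances are computed on canonical bipartition sets
(frozensets of the leaf labels on the side not containing a reference leaf),
normalized by twice the number of internal edges of a binary tree, 2(n-3).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import InvalidInputError
from .k2p import Alignment, pair_mismatch_counts, simulate_site_patterns
from .sr import SRFunction

__all__ = [
    "DissimilarityMap",
    "read_newick",
    "write_newick",
    "caterpillar_tree",
    "tree_diameter",
    "scale_tree_to_diameter",
    "distance_matrix",
    "neighbor_joining",
    "nj_bipartitions",
    "tree_bipartitions",
    "rf_distance",
    "normalized_rf",
    "read_phylip_matrix",
    "write_phylip_matrix",
]

DEFAULT_CAP = 5.0


@dataclass
class DissimilarityMap:
    """Symmetric leaf-pair dissimilarities with per-entry saturation flags."""

    labels: list[str]
    matrix: np.ndarray
    saturated: np.ndarray = field(default=None)  # boolean mask, True = capped

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise InvalidInputError("matrix shape does not match label count")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise InvalidInputError("dissimilarity matrix must be symmetric")
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)

    def __getitem__(self, pair):
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return self.matrix[i, j]


# ---------------------------------------------------------------------------
# Newick I/O and tree fixtures


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string (or handle) into an unrooted dendropy tree."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        raise InvalidInputError(f"malformed Newick input: {exc}") from exc
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize with enough digits to round-trip edge lengths exactly."""
    return tree.as_string(schema="newick", suppress_rooting=True,
                          real_value_format_specifier=".17g").strip()


def caterpillar_tree(n_leaves: int, t_int: float, t_ext: float) -> dendropy.Tree:
    """Caterpillar tree on ``n_leaves`` labeled L1..Ln: a chain of n-3
    internal edges of length ``t_int``, every leaf at ``t_ext``.

    Every internal node touches at least one external edge; the diameter is
    2 t_ext + (n-3) t_int.
    """
    if n_leaves < 4:
        raise InvalidInputError(f"caterpillar needs >= 4 leaves, got {n_leaves}")
    if t_int <= 0 or t_ext <= 0:
        raise InvalidInputError("edge times must be positive")
    core = f"(L1:{t_ext:.17g},L2:{t_ext:.17g})"
    for i in range(3, n_leaves - 1):
        core = f"({core}:{t_int:.17g},L{i}:{t_ext:.17g})"
    newick = f"({core}:{t_int:.17g},L{n_leaves - 1}:{t_ext:.17g},L{n_leaves}:{t_ext:.17g});"
    return read_newick(newick)


def tree_diameter(tree: dendropy.Tree) -> float:
    """Largest leaf-to-leaf path time."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    best = 0.0
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            best = max(best, float(pdm.patristic_distance(taxa[i], taxa[j])))
    return best


def scale_tree_to_diameter(tree: dendropy.Tree, s: float) -> dendropy.Tree:
    """Copy of the tree with all edges multiplied so the diameter equals s."""
    if s <= 0:
        raise InvalidInputError(f"target diameter must be positive, got {s}")
    diam = tree_diameter(tree)
    if diam <= 0:
        raise InvalidInputError("tree has zero diameter")
    out = tree.clone(depth=1)
    factor = s / diam
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * factor
    return out


# ---------------------------------------------------------------------------
# Distance matrices


def pairwise_stats_matrix(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """(p_alpha_hat, p_beta_hat) matrices for all pairs of an alignment."""
    from .k2p import _encode

    n = len(aln)
    coded = [_encode(s) for s in aln.sequences]
    k = aln.n_sites
    pa = np.zeros((n, n))
    pb = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            n_ti, n_tv = pair_mismatch_counts(coded[i], coded[j])
            pa[i, j] = pa[j, i] = n_ti / k
            pb[i, j] = pb[j, i] = n_tv / (2.0 * k)
    return pa, pb


def _cap_matrix(M: np.ndarray, default_cap: float = DEFAULT_CAP) -> tuple[np.ndarray, np.ndarray]:
    """Replace NaN entries by 2x the largest finite entry of the matrix."""
    sat = ~np.isfinite(M)
    np.fill_diagonal(sat, False)
    if not sat.any():
        return M, sat
    finite = M[np.isfinite(M) & ~np.eye(len(M), dtype=bool)]
    cap = 2.0 * finite.max() if finite.size else default_cap
    out = M.copy()
    out[sat] = cap
    return out, sat


def distance_matrix(aln: Alignment, delta: SRFunction,
                    cap_policy: str = "cap") -> DissimilarityMap:
    """Apply an SR function to the pairwise mismatch statistics.

    ``cap_policy="cap"`` replaces saturated entries by twice the largest
    finite distance in the matrix (5.0 if none); ``"raise"`` propagates the
    saturation error instead.
    """
    if len(aln) < 2:
        raise InvalidInputError("need at least two sequences")
    pa, pb = pairwise_stats_matrix(aln)
    D = delta.from_probs_array(pa, pb)
    np.fill_diagonal(D, 0.0)
    if cap_policy == "raise":
        if not np.all(np.isfinite(D)):
            from .errors import SaturationError

            raise SaturationError("saturated pairwise distance", bound="matrix")
        sat = np.zeros_like(D, dtype=bool)
    else:
        D, sat = _cap_matrix(D)
    return DissimilarityMap(list(aln.labels), D, sat)


# ---------------------------------------------------------------------------
# Neighbor joining


def _nj_merge_order(D: np.ndarray) -> list[tuple[int, int, float, float]]:
    """Run the NJ agglomeration on a working copy of D.

    Returns the merge list [(i, j, limb_i, limb_j), ...] in node indices
    where the original leaves are 0..n-1 and the merge at position m creates
    node n+m.  Ties in the Q criterion resolve to the smallest (i, j) in
    row-major order (np.argmin convention).
    """
    n = len(D)
    D = D.astype(float).copy()
    active = list(range(n))
    next_id = n
    merges: list[tuple[int, int, float, float]] = []
    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        merges.append((active[i], active[j], li, lj))
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        D = D2
        active = [active[x] for x in keep] + [next_id]
        next_id += 1
    # final three nodes join at a central vertex
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    merges.append((active[0], active[1], la, lb))
    merges.append((-1, active[2], 0.0, lc))  # sentinel: attach third to center
    return merges


def _nj_assemble(labels: list[str], merges) -> tuple[str, set[frozenset]]:
    """Newick string and canonical bipartition set from the merge list.

    Every regular merge creates one internal edge whose bipartition is the
    leaf set of the merged cluster; the terminal 3-way join adds no new
    internal edge, so the n-3 recorded splits are exactly the nontrivial
    bipartitions of the NJ topology.
    """
    n = len(labels)
    all_leaves = frozenset(labels)
    ref = min(labels)
    newicks: dict[int, str] = {i: labels[i] for i in range(n)}
    leafsets: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    splits: set[frozenset] = set()
    next_id = n
    for i, j, li, lj in merges[:-2]:
        merged = leafsets[i] | leafsets[j]
        side = frozenset(all_leaves - merged) if ref in merged else merged
        if 2 <= len(side) <= n - 2:
            splits.add(side)
        newicks[next_id] = f"({newicks[i]}:{li:.17g},{newicks[j]}:{lj:.17g})"
        leafsets[next_id] = merged
        next_id += 1
    a, b, la, lb = merges[-2]
    _, c, _, lc = merges[-1]
    newick = f"({newicks[a]}:{la:.17g},{newicks[b]}:{lb:.17g},{newicks[c]}:{lc:.17g});"
    return newick, splits


def neighbor_joining(D: DissimilarityMap) -> dendropy.Tree:
    """Classic neighbor joining (Q-criterion, Studier-Keppler updates).

    Deterministic: Q-ties break to the smallest row-major index pair.
    Negative branch lengths are retained (downstream evaluation is
    topology-only).  The topology is invariant to affine transformations
    a*D + b (a > 0) of the off-diagonal distances.
    """
    M = np.asarray(D.matrix, dtype=float)
    if len(D.labels) < 4:
        raise InvalidInputError("neighbor joining needs >= 4 leaves")
    if not np.all(np.isfinite(M)):
        raise InvalidInputError("non-finite distances; apply a cap policy first")
    merges = _nj_merge_order(M)
    newick, _ = _nj_assemble(list(D.labels), merges)
    return read_newick(newick)


def nj_bipartitions(matrix: np.ndarray, labels: list[str]) -> set[frozenset]:
    """Fast path: canonical bipartition set of the NJ topology, skipping
    tree-object construction (used by the replicated experiment drivers)."""
    merges = _nj_merge_order(np.asarray(matrix, dtype=float))
    _, splits = _nj_assemble(list(labels), merges)
    return splits


# ---------------------------------------------------------------------------
# Robinson-Foulds


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Canonical nontrivial bipartitions of an unrooted tree."""
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    all_leaves = frozenset(labels)
    ref = min(labels)
    n = len(labels)
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = frozenset(all_leaves - below) if ref in below else below
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    two trees' nontrivial bipartition sets."""
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        raise InvalidInputError("trees must share the same leaf set")
    return len(tree_bipartitions(t1) ^ tree_bipartitions(t2))


def normalized_rf(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    """RF distance divided by its maximum 2(n-3) for binary unrooted trees."""
    n = sum(1 for _ in t1.leaf_node_iter())
    if n < 4:
        raise InvalidInputError("normalized RF needs >= 4 leaves")
    return rf_distance(t1, t2) / (2.0 * (n - 3))


# ---------------------------------------------------------------------------
# PHYLIP square matrices


def write_phylip_matrix(D: DissimilarityMap) -> str:
    lines = [f"{len(D.labels):5d}"]
    for lab, row in zip(D.labels, D.matrix):
        name = f"{lab[:10]:<10s}"
        lines.append(name + "  " + "  ".join(f"{v:.6f}" for v in row))
    return "\n".join(lines) + "\n"


def read_phylip_matrix(text: str) -> DissimilarityMap:
    handle = io.StringIO(text)
    first = handle.readline().split()
    if not first:
        raise InvalidInputError("empty PHYLIP matrix")
    n = int(first[0])
    labels, rows = [], []
    for line in handle:
        if not line.strip():
            continue
        parts = line.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    if len(labels) != n:
        raise InvalidInputError(f"expected {n} rows, found {len(labels)}")
    return DissimilarityMap(labels, np.asarray(rows))


# ---------------------------------------------------------------------------
# Replicated simulation helper for tree-scale experiments


def simulated_rf_multi(tree: dendropy.Tree, deltas: list[SRFunction], R: float,
                       k: int, reps: int, rng: np.random.Generator,
                       batch: int = 2000) -> dict[str, np.ndarray]:
    """Normalized RF to the true tree for ``reps`` simulate->distances->NJ
    replicates, for several SR functions on the *same* simulated alignments
    (paired design).  Simulation and pairwise statistics are vectorized;
    saturated distances are capped per replicate matrix."""
    from .quartets import apply_cap

    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    n = len(labels)
    true_splits = tree_bipartitions(tree)
    max_rf = 2.0 * (n - 3)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    iu = np.triu_indices(n, 1)
    out = {d.name: np.empty(reps) for d in deltas}
    done = 0
    while done < reps:
        b = min(batch, reps - done)
        leaves = simulate_site_patterns(tree, R, k, b, rng)
        pa = np.empty((b, len(pairs)))
        pb = np.empty((b, len(pairs)))
        for idx, (i, j) in enumerate(pairs):
            n_ti, n_tv = pair_mismatch_counts(leaves[labels[i]], leaves[labels[j]])
            pa[:, idx] = n_ti / k
            pb[:, idx] = n_tv / (2.0 * k)
        for d in deltas:
            dists, _ = apply_cap(d.from_probs_array(pa, pb))
            for r in range(b):
                M = np.zeros((n, n))
                M[iu] = dists[r]
                M += M.T
                splits = nj_bipartitions(M, labels)
                out[d.name][done + r] = len(splits ^ true_splits) / max_rf
        done += b
    return out


def simulated_rf_series(tree: dendropy.Tree, delta: SRFunction, R: float,
                        k: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """Single-SR convenience wrapper around :func:`simulated_rf_multi`."""
    return simulated_rf_multi(tree, [delta], R, k, reps, rng)[delta.name]
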