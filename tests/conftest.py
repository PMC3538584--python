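import numpy as np
import pytest

import phylosr as ps


@pytest.fixture
def rng():
    return np.random.default_rng(20120831)


@pytest.fixture
def quartet_b():
    """A type-B quartet with a mild transition bias."""
    return ps.QuartetModel("B", t_i=0.2, t_s=0.4, t_l=1.0, R=5.0)


@pytest.fixture
def caterpillar7():
    """Semi-symmetric 7-taxon caterpillar (external edges 5x internal)."""
    return ps.caterpillar_tree(7, t_int=0.1, t_ext=0.5)


def random_binary_tree(n_leaves: int, rng: np.random.Generator):
    """Random binary topology with uniform random edge times in [0.05, 0.5]."""
    from phylosr.trees import read_newick

    def el():
        return 0.05 + 0.45 * rng.random()

    subtrees = [f"L{i + 1}:{el():.6f}" for i in range(n_leaves)]
    while len(subtrees) > 3:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        subtrees.append(f"({a},{b}):{el():.6f}")
    return read_newick("(" + ",".join(subtrees) + ");")


def exact_distance_map(tree) -> ps.DissimilarityMap:
    """True path-time dissimilarity map of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda x: x.label)
    labels = [x.label for x in taxa]
    M = np.array([[0.0 if a is b else pdm.patristic_distance(a, b)
                   for b in taxa] for a in taxa])
    return ps.DissimilarityMap(labels, M)
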