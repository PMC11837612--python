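import numpy as np
import pytest

from genovmap.io_formats import OrthogroupTable, phylogeny_from_newick_string


@pytest.fixture
def five_leaf_tree():
    """(((A,B),(C,D)),E); with preorder internal labels N1..N4."""
    return phylogeny_from_newick_string("(((A,B),(C,D)),E);")


@pytest.fixture
def small_table():
    return OrthogroupTable(
        species=["A", "B", "C", "D", "E"],
        groups={
            "OG1": {"A": ["a1", "a2"], "B": ["b1"], "C": ["c1"],
                    "D": [], "E": []},
            "OG2": {"A": ["a3"], "B": [], "C": [], "D": [], "E": []},
            "OG3": {"A": ["a4"], "B": ["b2"], "C": ["c2"], "D": ["d1"],
                    "E": ["e1"]},
            "OG4": {"A": [], "B": [], "C": ["c3"], "D": ["d2"], "E": []},
        },
    )


def random_phylogeny(rng: np.random.Generator, n_leaves: int):
    """Random rooted bifurcating tree with leaves L1..Ln."""
    from genovmap.synthetic_data import random_tree

    names = [f"L{i+1}" for i in range(n_leaves)]
    return phylogeny_from_newick_string(random_tree(names, rng))


def bruteforce_mrca(tree, leaf_set):
    """Independent oracle: intersect root-to-leaf paths and take the
    deepest shared node."""
    paths = [set(tree.path_to_root(lf)) for lf in leaf_set]
    common = set.intersection(*paths)
    return max(common, key=tree.depth)
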