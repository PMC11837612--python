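import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genovmap.gain_mapping import (
    assign_gains,
    filter_min_species,
    mrca,
    orthogroups_at,
    rescue_against_alternative_annotation,
)
from genovmap.io_formats import HitRecord, OrthogroupTable
from genovmap.synthetic_data import SimConfig, default_tree, simulate_families

from conftest import bruteforce_mrca, random_phylogeny


def _hit(pid, ev, qc, sc, q="g", s="x"):
    return HitRecord(q, s, pid, ev, qc, sc, "other_metazoa")


# -- species-count filter ------------------------------------------------------


def test_filter_boundary_two_vs_three_species(small_table):
    retained, excluded = filter_min_species(small_table, min_species=3)
    # OG1 spans 3 species (kept), OG2 one, OG4 two (excluded)
    assert set(retained.orthogroup_ids) == {"OG1", "OG3"}
    assert set(excluded) == {"OG2", "OG4"}


def test_filter_partitions_random_tables():
    tree, _ = default_tree(3, n_focal=10, n_outgroup=3)
    table, _ = simulate_families(SimConfig(seed=3, tree=tree,
                                           n_orthogroups=60, loss_prob=0.3))
    retained, excluded = filter_min_species(table)
    assert len(retained.orthogroup_ids) + len(excluded) == 60
    assert set(retained.orthogroup_ids).isdisjoint(excluded)
    assert all(len(retained.presence_set(og)) >= 3
               for og in retained.orthogroup_ids)


def test_filter_rejects_min_species_below_one(small_table):
    with pytest.raises(ValueError):
        filter_min_species(small_table, min_species=0)


# -- MRCA ----------------------------------------------------------------------


def test_mrca_trivial_cases(five_leaf_tree):
    t = five_leaf_tree
    assert mrca(t, t.leaves) == t.root
    assert mrca(t, ["C"]) == "C"
    assert mrca(t, ["A", "B"]) == mrca(t, ["B", "A"])


def test_mrca_unknown_leaf_named(five_leaf_tree):
    with pytest.raises(KeyError, match="ZZZ"):
        mrca(five_leaf_tree, ["A", "ZZZ"])


def test_mrca_equals_path_intersection_oracle():
    """Random trees x random presence sets: agrees with the brute-force
    root-path intersection."""
    rng = np.random.default_rng(0)
    for _ in range(25):
        t = random_phylogeny(rng, int(rng.integers(4, 40)))
        leaves = t.leaves
        for _ in range(20):
            k = int(rng.integers(1, len(leaves) + 1))
            sub = list(rng.choice(leaves, size=k, replace=False))
            assert mrca(t, sub) == bruteforce_mrca(t, sub)


def test_mrca_monotone_under_leaf_addition():
    """Adding leaves to a presence set never yields a more recent MRCA."""
    rng = np.random.default_rng(1)
    t = random_phylogeny(rng, 30)
    leaves = t.leaves
    for _ in range(50):
        k = int(rng.integers(1, 15))
        sub = list(rng.choice(leaves, size=k, replace=False))
        node = mrca(t, sub)
        extra = list(rng.choice(leaves, size=3, replace=False))
        bigger = mrca(t, sub + extra)
        assert t.is_ancestor_or_equal(bigger, node)


_PROP_TREE = random_phylogeny(np.random.default_rng(99), 20)


@settings(max_examples=80, derandomize=True)
@given(sub=st.sets(st.sampled_from(_PROP_TREE.leaves), min_size=1,
                   max_size=20))
def test_mrca_covers_all_input_leaves(sub):
    """The MRCA's descendant leaf set always contains the presence set."""
    node = mrca(_PROP_TREE, sub)
    assert sub <= _PROP_TREE.leaf_set(node)
    # and no child of the MRCA still covers the whole set (deepest such node)
    for child in _PROP_TREE.children.get(node, []):
        assert not (sub <= _PROP_TREE.leaf_set(child))


# -- gain assignment -----------------------------------------------------------


def test_clade_specific_orthogroup_maps_to_clade_root():
    tree, focal = default_tree(5, n_focal=8, n_outgroup=3)
    focal_node = mrca(tree, focal)
    table = OrthogroupTable(
        species=tree.leaves,
        groups={"OGx": {sp: (["g_" + sp] if sp in focal else [])
                        for sp in tree.leaves}})
    gm = assign_gains(tree, table)
    assert gm.assignments["OGx"] == focal_node
    assert tree.parent[focal_node] == tree.root  # the branch to the clade


def test_root_spanning_set_maps_to_root(five_leaf_tree):
    table = OrthogroupTable(
        species=five_leaf_tree.leaves,
        groups={"OGr": {"A": ["a"], "B": [], "C": [], "D": [], "E": ["e"]}})
    gm = assign_gains(five_leaf_tree, table)
    assert gm.assignments["OGr"] == five_leaf_tree.root


def test_species_missing_from_tree_listed(five_leaf_tree):
    table = OrthogroupTable(species=["A", "Zz"],
                            groups={"OG1": {"A": ["a"], "Zz": ["z"]}})
    with pytest.raises(ValueError, match="Zz"):
        assign_gains(five_leaf_tree, table)


def test_zero_loss_simulation_recovers_gain_nodes_exactly():
    tree, _ = default_tree(9, n_focal=20, n_outgroup=5)
    table, truth = simulate_families(
        SimConfig(seed=9, tree=tree, n_orthogroups=100, loss_prob=0.0,
                  dup_rate=0.1))
    gm = assign_gains(tree, table)
    assert all(gm.assignments[og] == truth.gain_node[og]
               for og in table.orthogroup_ids)


def test_inference_never_more_ancient_than_truth_under_loss():
    tree, _ = default_tree(10, n_focal=30, n_outgroup=6)
    table, truth = simulate_families(
        SimConfig(seed=10, tree=tree, n_orthogroups=150, loss_prob=0.15))
    for og in table.orthogroup_ids:
        if not table.presence_set(og):
            continue
        inferred = mrca(tree, table.presence_set(og))
        assert tree.is_ancestor_or_equal(truth.gain_node[og], inferred)


# -- per-node extraction ---------------------------------------------------------


def test_orthogroups_at_partition(five_leaf_tree, small_table):
    gm = assign_gains(five_leaf_tree, small_table)
    total = sum(len(orthogroups_at(gm, n, five_leaf_tree))
                for n in five_leaf_tree.nodes)
    assert total == len(gm.assignments)
    # hand-placed: OG1 spans A,B,C -> N2; OG3 spans all -> root; OG4 -> CD clade
    assert orthogroups_at(gm, "N1", five_leaf_tree) == ["OG3"]
    assert "OG1" in orthogroups_at(gm, "N2", five_leaf_tree)


def test_orthogroups_at_unknown_node(five_leaf_tree, small_table):
    gm = assign_gains(five_leaf_tree, small_table)
    with pytest.raises(KeyError):
        orthogroups_at(gm, "NOPE", five_leaf_tree)
    assert orthogroups_at(gm, "E", five_leaf_tree) == []


# -- rescue against alternative annotations ---------------------------------------


def test_rescue_demotes_on_passing_hit():
    confirmed, demoted = rescue_against_alternative_annotation(
        ["OG1", "OG2"], [_hit(30.0, 1e-6, 65.0, 70.0, q="OG1")])
    assert demoted == ["OG1"]
    assert confirmed == ["OG2"]


def test_rescue_identity_boundary_is_strict():
    # identity exactly 25 is not "above 25%": no demotion
    confirmed, demoted = rescue_against_alternative_annotation(
        ["OG1"], [_hit(25.0, 1e-6, 65.0, 70.0, q="OG1")])
    assert confirmed == ["OG1"] and demoted == []
    # but coverage exactly 60 passes (inclusive)
    _, demoted = rescue_against_alternative_annotation(
        ["OG1"], [_hit(26.0, 1e-6, 60.0, 60.0, q="OG1")])
    assert demoted == ["OG1"]


def test_rescue_partitions_candidates():
    rng = np.random.default_rng(4)
    cands = [f"OG{i}" for i in range(40)]
    hits = [_hit(float(rng.uniform(10, 60)), 10.0 ** rng.uniform(-9, -3),
                 float(rng.uniform(40, 90)), float(rng.uniform(40, 90)),
                 q=cands[rng.integers(40)])
            for _ in range(200)]
    confirmed, demoted = rescue_against_alternative_annotation(cands, hits)
    assert sorted(confirmed + demoted) == sorted(cands)
    assert set(confirmed).isdisjoint(demoted)
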