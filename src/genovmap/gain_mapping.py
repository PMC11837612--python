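"""Assign each orthogroup's node of origin on the species tree by MRCA parsimony.

The dating rule is the parsimony assumption of phylostratigraphy: the common
ancestor of all species possessing a family is its node of origin. A gain
reported on a node is equivalently a gain on the branch leading to that node.

Under per-branch gene loss the rule is conservative in one direction only:
loss removes leaves from the presence set, so the inferred node can drift
*toward the leaves* within the true gain clade but can never become more
ancient than the true origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import HitRecord, OrthogroupTable, Phylogeny

__all__ = [
    "GainMap",
    "filter_min_species",
    "mrca",
    "assign_gains",
    "orthogroups_at",
    "rescue_against_alternative_annotation",
]


@dataclass
class GainMap:
    """Result of gain-node assignment.

    ``assignments`` maps every retained orthogroup to exactly one node of the
    tree; ``node_counts`` are per-node totals; ``excluded`` lists orthogroups
    removed by the minimum-species filter.
    """

    assignments: dict[str, str]
    node_counts: dict[str, int]
    excluded: list[str] = field(default_factory=list)


def filter_min_species(
    table: OrthogroupTable, min_species: int = 3
) -> tuple[OrthogroupTable, list[str]]:
    """Partition orthogroups by presence-set size.

    The default of 3 retains families present in more than two species; the
    excluded list is preserved for reporting. ``retained + excluded`` is
    always the full input set.
    """
    if min_species < 1:
        raise ValueError(f"min_species must be >= 1, got {min_species}")
    retained = [og for og in table.orthogroup_ids
                if len(table.presence_set(og)) >= min_species]
    excluded = [og for og in table.orthogroup_ids
                if len(table.presence_set(og)) < min_species]
    return table.subset(retained), excluded


def mrca(tree: Phylogeny, leaf_set: Iterable[str]) -> str:
    """Most recent common ancestor of *leaf_set*.

    Returns the deepest node whose leaf descendants contain every member of
    the set; a singleton set maps to its own leaf.
    """
    leaves = list(leaf_set)
    if not leaves:
        raise ValueError("leaf_set must be non-empty")
    for lf in leaves:
        if lf not in tree.parent:
            raise KeyError(f"unknown leaf: {lf!r}")
        if not tree.is_leaf(lf):
            raise ValueError(f"{lf!r} is not a leaf")
    node = leaves[0]
    for lf in leaves[1:]:
        a, b = node, lf
        da, db = tree.depth(a), tree.depth(b)
        while da > db:
            a = tree.parent[a]  # type: ignore[assignment]
            da -= 1
        while db > da:
            b = tree.parent[b]  # type: ignore[assignment]
            db -= 1
        while a != b:
            a = tree.parent[a]  # type: ignore[assignment]
            b = tree.parent[b]  # type: ignore[assignment]
        node = a
    return node


def assign_gains(tree: Phylogeny, table: OrthogroupTable,
                 min_species: int | None = None) -> GainMap:
    """Map every orthogroup to its gain node (MRCA of its presence set).

    If *min_species* is given the table is filtered first and excluded
    orthogroups are recorded on the returned :class:`GainMap`. Species present
    in the table but absent from the tree are a hard error.
    """
    missing = sorted(set(table.species) - set(tree.leaves))
    if missing:
        raise ValueError(f"species absent from tree: {missing}")
    excluded: list[str] = []
    if min_species is not None:
        table, excluded = filter_min_species(table, min_species)
    assignments: dict[str, str] = {}
    counts: dict[str, int] = {}
    for og in table.orthogroup_ids:
        present = table.presence_set(og)
        if not present:
            raise ValueError(f"{og}: empty presence set; filter first")
        node = mrca(tree, present)
        assignments[og] = node
        counts[node] = counts.get(node, 0) + 1
    return GainMap(assignments=assignments, node_counts=counts,
                   excluded=excluded)


def orthogroups_at(gain_map: GainMap, node_id: str,
                   tree: Phylogeny | None = None) -> list[str]:
    """Sorted orthogroup IDs assigned to *node_id*.

    If *tree* is supplied, unknown nodes raise; otherwise any node absent from
    the map's assignments simply yields an empty list unless it is unknown to
    the map entirely and no tree is available to validate it.
    """
    if tree is not None and node_id not in tree.parent:
        raise KeyError(f"unknown node: {node_id!r}")
    if tree is None and node_id not in gain_map.node_counts \
            and node_id not in set(gain_map.assignments.values()):
        # without a tree we can only validate against observed nodes; an
        # unobserved node is allowed solely when a tree confirms it exists
        raise KeyError(f"unknown node: {node_id!r} (no tree supplied)")
    return sorted(og for og, nd in gain_map.assignments.items()
                  if nd == node_id)


def rescue_against_alternative_annotation(
    candidate_ogs: Sequence[str],
    outgroup_hits: Iterable[HitRecord],
    query_to_og: Mapping[str, str] | None = None,
    max_evalue: float = 1e-5,
    min_identity: float = 25.0,
    min_coverage: float = 60.0,
) -> tuple[list[str], list[str]]:
    """Cross-check clade-specific candidates against an alternative outgroup
    annotation (e.g. a BRAKER re-annotation of the sister clade's genomes).

    A candidate with at least one hit passing all thresholds is *demoted* (a
    homologue exists outside the clade after all); the rest are *confirmed*.
    Boundary semantics: e-value <= cutoff, identity strictly above the cutoff
    ("above 25%"), both coverages >= the cutoff.

    *query_to_og* maps hit query IDs (member genes) to their orthogroup; when
    omitted, query IDs are taken to be orthogroup IDs already.
    """
    cand = set(candidate_ogs)
    demoted: set[str] = set()
    for h in outgroup_hits:
        og = query_to_og.get(h.query_id) if query_to_og is not None \
            else h.query_id
        if og is None or og not in cand:
            continue
        if (h.evalue <= max_evalue
                and h.percent_identity > min_identity
                and h.query_coverage_pct >= min_coverage
                and h.subject_coverage_pct >= min_coverage):
            demoted.add(og)
    confirmed = [og for og in candidate_ogs if og not in demoted]
    return confirmed, sorted(demoted)
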