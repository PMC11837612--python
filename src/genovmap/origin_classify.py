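"""Classify each clade-specific orthogroup's likely mode of origin.

Three mutually exclusive labels are assigned from filtered homology evidence
and protein-domain annotation:

* ``duplication_divergence`` — a passing hit against metazoan proteomes
  outside the focal clade, or a known protein domain: the family descends
  from a pre-existing gene that diverged beyond orthology detection.
* ``hgt`` — passing hits only against non-metazoan subjects: presence in the
  focal clade and non-metazoan proteomes but absence from other animals is
  the signature of horizontal transfer.
* ``de_novo_candidate`` — no passing hits anywhere and no known domain: an
  orphan family, a candidate for de novo origin from non-coding sequence.

Metazoan evidence takes precedence over non-metazoan evidence: a family with
hits in both cannot be called HGT, because animal homologues outside the
focal clade are positive evidence for vertical descent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .io_formats import DomainAnnotation, HitRecord
from .gain_mapping import GainMap

__all__ = [
    "ORIGIN_LABELS",
    "OriginCall",
    "OrthogroupLinkSet",
    "filter_hits",
    "classify_origin",
    "link_orthogroups",
    "summarize_modes",
]

ORIGIN_LABELS = ("duplication_divergence", "hgt", "de_novo_candidate")

# below this query coverage a passing hit is annotated as partial homology
PARTIAL_QCOV = 45.0


@dataclass
class OriginCall:
    orthogroup_id: str
    label: str
    n_metazoan_hits: int = 0
    n_nonmetazoan_hits: int = 0
    domain_accessions: list[str] = field(default_factory=list)
    n_partial_hits: int = 0

    def __post_init__(self) -> None:
        if self.label not in ORIGIN_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if min(self.n_metazoan_hits, self.n_nonmetazoan_hits,
               self.n_partial_hits) < 0:
            raise ValueError("evidence counts must be >= 0")


@dataclass
class OrthogroupLinkSet:
    """Orthogroups connected to a seed through reciprocal-similarity links."""

    seed: str
    linked: list[str]
    linking_hits: list[HitRecord] = field(default_factory=list)

    @property
    def component(self) -> frozenset[str]:
        return frozenset([self.seed, *self.linked])


def _check_thresholds(max_evalue: float, min_identity: float,
                      min_qcov: float, min_scov: float) -> None:
    if max_evalue < 0:
        raise ValueError("max_evalue must be >= 0")
    for name, v in (("min_identity", min_identity), ("min_qcov", min_qcov),
                    ("min_scov", min_scov)):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name}={v} outside [0, 100]")


def filter_hits(
    hits: Iterable[HitRecord],
    max_evalue: float = 1e-5,
    min_identity: float = 25.0,
    min_qcov: float = 60.0,
    min_scov: float = 60.0,
) -> list[HitRecord]:
    """Remove partial-homology hits.

    A record is kept iff e-value <= *max_evalue*, identity strictly above
    *min_identity* ("above 25%"), and both coverages >= the minima. Tightening
    any threshold never adds records.
    """
    _check_thresholds(max_evalue, min_identity, min_qcov, min_scov)
    return [h for h in hits
            if h.evalue <= max_evalue
            and h.percent_identity > min_identity
            and h.query_coverage_pct >= min_qcov
            and h.subject_coverage_pct >= min_scov]


def classify_origin(
    orthogroup_id: str,
    member_genes: Iterable[str],
    domains: DomainAnnotation,
    metazoan_hits: Sequence[HitRecord],
    nonmetazoan_hits: Sequence[HitRecord],
    domain_evalue: float = 1e-3,
    domain_alone_is_duplication: bool = True,
) -> OriginCall:
    """Label one orthogroup's likely mode of origin.

    *metazoan_hits* and *nonmetazoan_hits* must already be filtered and must
    exclude the focal clade; a ``focal_clade`` record in either input is a
    leakage error. Evidence is counted over any member gene of the orthogroup.

    Decision order: metazoan hit or known domain -> duplication_divergence;
    else non-metazoan hit -> hgt; else de_novo_candidate. Set
    *domain_alone_is_duplication* to False to require a sequence hit for the
    duplication label (a domain with no hit then falls through).
    """
    for h in list(metazoan_hits) + list(nonmetazoan_hits):
        if h.subject_taxon_class == "focal_clade":
            raise ValueError(
                f"{orthogroup_id}: focal-clade hit {h.subject_id!r} in an "
                "outside-clade evidence table (leakage)")
    genes = set(member_genes)
    met = [h for h in metazoan_hits if h.query_id in genes]
    non = [h for h in nonmetazoan_hits if h.query_id in genes]
    accs = domains.for_genes(genes, max_evalue=domain_evalue)
    n_partial = sum(1 for h in met + non
                    if h.query_coverage_pct < PARTIAL_QCOV)

    if met or (accs and domain_alone_is_duplication):
        label = "duplication_divergence"
    elif non:
        label = "hgt"
    else:
        label = "de_novo_candidate"
    return OriginCall(
        orthogroup_id=orthogroup_id,
        label=label,
        n_metazoan_hits=len(met),
        n_nonmetazoan_hits=len(non),
        domain_accessions=accs,
        n_partial_hits=n_partial,
    )


def link_orthogroups(
    seed_og: str,
    all_ogs: Iterable[str],
    cross_og_hits: Iterable[HitRecord],
    gene_to_og: Mapping[str, str],
    min_identity: float = 25.0,
    min_cov: float = 60.0,
    max_evalue: float | None = None,
) -> OrthogroupLinkSet:
    """Merge homologous orthogroups by member-vs-member similarity links.

    Two orthogroups are linked by any hit between their member proteins with
    identity and both coverages *equal to or above* the thresholds (contrast
    with :func:`filter_hits`, whose identity rule is strict). The result is
    the connected component containing the seed, so it is independent of
    which member of a component seeds the search.
    """
    ogs = set(all_ogs)
    if seed_og not in ogs:
        raise KeyError(f"seed {seed_og!r} not among orthogroups")
    g = nx.Graph()
    g.add_nodes_from(ogs)
    linking: list[HitRecord] = []
    for h in cross_og_hits:
        qa = gene_to_og.get(h.query_id)
        qb = gene_to_og.get(h.subject_id)
        if qa is None or qb is None or qa not in ogs or qb not in ogs:
            continue
        if qa == qb:
            continue
        if (h.percent_identity >= min_identity
                and h.query_coverage_pct >= min_cov
                and h.subject_coverage_pct >= min_cov
                and (max_evalue is None or h.evalue <= max_evalue)):
            g.add_edge(qa, qb)
            linking.append(h)
    comp = nx.node_connected_component(g, seed_og)
    keep = {og for pair in ((gene_to_og.get(h.query_id),
                             gene_to_og.get(h.subject_id))
                            for h in linking) for og in pair}
    return OrthogroupLinkSet(
        seed=seed_og,
        linked=sorted(comp - {seed_og}),
        linking_hits=[h for h in linking
                      if gene_to_og[h.query_id] in comp
                      and gene_to_og[h.subject_id] in comp],
    )


def summarize_modes(
    calls: Iterable[OriginCall],
    gain_map: GainMap,
) -> pd.DataFrame:
    """Count origin labels per gain node.

    Returns a node x label table whose rows sum to the node's gain count for
    the classified cohort; a call without a gain assignment is an error.
    """
    rows = []
    for c in calls:
        node = gain_map.assignments.get(c.orthogroup_id)
        if node is None:
            raise KeyError(
                f"{c.orthogroup_id}: classified but has no gain assignment")
        rows.append((node, c.label))
    if not rows:
        return pd.DataFrame(columns=list(ORIGIN_LABELS)).rename_axis("node")
    df = pd.DataFrame(rows, columns=["node", "label"])
    out = (df.groupby(["node", "label"]).size().unstack(fill_value=0)
           .reindex(columns=list(ORIGIN_LABELS), fill_value=0))
    out["total"] = out.sum(axis=1)
    return out
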