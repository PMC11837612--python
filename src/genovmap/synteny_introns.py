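"""Microsynteny conservation via flanking marker genes, and intron summaries.

A gene's *marker context* is its nearest neighbours on the chromosome (two
each side by default), ordered by start coordinate and strand-agnostic. Two
species conserve a target's integration site when the markers around one
species' copy have homologues near the other species' copy: the shared-marker
count is computed in both directions through a homology map (orthogroup
membership) and the reported count is the smaller of the two, which makes the
comparison symmetric and bounded by the smaller flank size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import GeneModel

__all__ = [
    "MarkerContext",
    "SyntenyComparison",
    "marker_context",
    "compare_synteny",
    "intron_summary",
]


@dataclass
class MarkerContext:
    """A target gene with its ordered flanking markers and a wider window
    neighbourhood used when testing whether another species' markers land
    near this target."""

    target_gene: str
    species: str
    chromosome: str
    upstream: list[str]      # nearest first going away from the target
    downstream: list[str]
    neighborhood: list[str]  # genes within `window` positions, both sides
    truncated: bool = False  # fewer flanks than requested were available

    @property
    def markers(self) -> list[str]:
        return [*self.upstream, *self.downstream]


@dataclass
class SyntenyComparison:
    species_a: str
    species_b: str
    target_a: str
    target_b: str
    shared_count: int
    max_possible: int
    conserved: bool
    shared_a_in_b: int = 0
    shared_b_in_a: int = 0


def _chromosome_order(models: Sequence[GeneModel],
                      chromosome: str) -> list[GeneModel]:
    return sorted((m for m in models if m.chromosome == chromosome),
                  key=lambda m: (m.start, m.end, m.gene_id))


def marker_context(
    gene_models: Sequence[GeneModel],
    target_gene: str,
    n_flank: int = 2,
    window: int = 10,
) -> MarkerContext:
    """Extract the *n_flank* nearest genes each side of *target_gene*.

    Neighbours are taken in coordinate order on the target's chromosome,
    ignoring strand. If the target sits near a chromosome end the context is
    truncated and flagged. *window* controls the wider neighbourhood recorded
    for cross-species comparison.
    """
    if n_flank < 1:
        raise ValueError("n_flank must be >= 1")
    if window < n_flank:
        raise ValueError("window must be >= n_flank")
    target = next((m for m in gene_models if m.gene_id == target_gene), None)
    if target is None:
        raise KeyError(f"target {target_gene!r} not in gene models")
    order = _chromosome_order(gene_models, target.chromosome)
    pos = next(i for i, m in enumerate(order) if m.gene_id == target_gene)
    up = [m.gene_id for m in order[max(0, pos - n_flank):pos]][::-1]
    down = [m.gene_id for m in order[pos + 1:pos + 1 + n_flank]]
    hood_lo = max(0, pos - window)
    hood = [m.gene_id for m in order[hood_lo:pos + 1 + window]
            if m.gene_id != target_gene]
    return MarkerContext(
        target_gene=target_gene,
        species=target.species,
        chromosome=target.chromosome,
        upstream=up,
        downstream=down,
        neighborhood=hood,
        truncated=(len(up) < n_flank or len(down) < n_flank),
    )


def _directional_shared(markers: Iterable[str], hood: Iterable[str],
                        homology_map: Mapping[str, str]) -> int:
    hood_classes = {homology_map[g] for g in hood if g in homology_map}
    n = 0
    for m in markers:
        cls = homology_map.get(m)
        if cls is not None and cls in hood_classes:
            n += 1
    return n


def compare_synteny(
    ctx_a: MarkerContext,
    ctx_b: MarkerContext,
    homology_map: Mapping[str, str],
    min_shared: int = 2,
) -> SyntenyComparison:
    """Compare two species' neighbourhoods around orthologous targets.

    *homology_map* assigns each gene its homology class (orthogroup ID); two
    genes are homologous iff they share a class. A marker of one context is
    "shared" when a homologue lies in the other context's window
    neighbourhood. The symmetric shared count is the minimum of the two
    directional counts; the verdict is conserved iff it reaches *min_shared*.
    """
    if ctx_a.species == ctx_b.species:
        raise ValueError(
            f"contexts are from the same species {ctx_a.species!r}")
    a_in_b = _directional_shared(ctx_a.markers, ctx_b.neighborhood,
                                 homology_map)
    b_in_a = _directional_shared(ctx_b.markers, ctx_a.neighborhood,
                                 homology_map)
    shared = min(a_in_b, b_in_a)
    max_possible = min(len(ctx_a.markers), len(ctx_b.markers))
    return SyntenyComparison(
        species_a=ctx_a.species,
        species_b=ctx_b.species,
        target_a=ctx_a.target_gene,
        target_b=ctx_b.target_gene,
        shared_count=shared,
        max_possible=max_possible,
        conserved=shared >= min_shared,
        shared_a_in_b=a_in_b,
        shared_b_in_a=b_in_a,
    )


def intron_summary(
    gene_models: Sequence[GeneModel],
    family_members: Mapping[str, Sequence[str]] | Sequence[str],
) -> tuple[pd.DataFrame, dict[str, float], list[str]]:
    """Intron counts per family gene and the per-subfamily median.

    *family_members* is either a flat gene list (one unnamed subfamily) or a
    mapping subfamily -> gene list. Intron count is exon count minus one on
    the longest transcript. Members absent from the models are returned in a
    missing list rather than raising.

    Returns ``(per_gene_table, per_subfamily_median, missing)``.
    """
    if not isinstance(family_members, Mapping):
        family_members = {"family": list(family_members)}
    by_id = {m.gene_id: m for m in gene_models}
    rows = []
    missing: list[str] = []
    medians: dict[str, float] = {}
    for subfam, genes in family_members.items():
        counts = []
        for g in genes:
            m = by_id.get(g)
            if m is None:
                missing.append(g)
                continue
            n_introns = m.intron_count
            counts.append(n_introns)
            rows.append((subfam, g, m.species, n_introns))
        if counts:
            medians[subfam] = float(median(counts))
    table = pd.DataFrame(
        rows, columns=["subfamily", "gene_id", "species", "introns"])
    return table, medians, missing
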