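"""Readers, writers and domain types for every external format the pipeline touches.

All downstream modules consume only the types defined here: :class:`Phylogeny`,
:class:`OrthogroupTable`, :class:`HitRecord`, :class:`DomainAnnotation`,
:class:`GeneModel` and :class:`ExpressionMatrix`.

Conventions
-----------
* Coordinates are 1-based inclusive (GFF3 convention); a span of length L from
  ``start`` to ``end`` satisfies ``end - start + 1 == L``.
* All tabular files are UTF-8 TSV; no CSV dialect sniffing is attempted.
* Internal tree nodes without newick labels receive deterministic preorder
  labels ``N1..Nk`` so that gain assignments are reproducible across runs.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

__all__ = [
    "Phylogeny",
    "OrthogroupTable",
    "HitRecord",
    "DomainAnnotation",
    "GeneModel",
    "ExpressionMatrix",
    "TAXON_CLASSES",
    "read_newick",
    "write_newick",
    "read_orthogroups",
    "write_orthogroups",
    "read_hits",
    "read_taxon_map",
    "read_domains",
    "read_gff",
    "read_expression",
]

TAXON_CLASSES = ("focal_clade", "other_metazoa", "non_metazoa")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


@dataclass
class Phylogeny:
    """A rooted tree over uniquely named nodes.

    Leaves carry species names exactly as they appear in the orthogroup table
    header; internal nodes carry unique string IDs. The tree is the coordinate
    system for all gain-node assignments.
    """

    root: str
    parent: dict[str, str | None]
    children: dict[str, list[str]]
    _depth: dict[str, int] = field(default_factory=dict, repr=False)
    _leafsets: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.parent.get(self.root) is not None:
            raise ValueError("root must have no parent")
        roots = [n for n, p in self.parent.items() if p is None]
        if roots != [self.root] and set(roots) != {self.root}:
            raise ValueError(f"exactly one root expected, found {roots}")

    # -- basic structure ----------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self.parent)

    def is_leaf(self, node: str) -> bool:
        return not self.children.get(node)

    @property
    def leaves(self) -> list[str]:
        return [n for n in self.preorder() if self.is_leaf(n)]

    @property
    def internal_nodes(self) -> list[str]:
        return [n for n in self.preorder() if not self.is_leaf(n)]

    def preorder(self) -> Iterable[str]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(self.children.get(node, [])))

    def depth(self, node: str) -> int:
        """Number of edges between *node* and the root."""
        if not self._depth:
            for n in self.preorder():
                p = self.parent[n]
                self._depth[n] = 0 if p is None else self._depth[p] + 1
        return self._depth[node]

    def path_to_root(self, node: str) -> list[str]:
        """Nodes from *node* up to and including the root."""
        if node not in self.parent:
            raise KeyError(f"unknown node: {node!r}")
        path = [node]
        while (p := self.parent[path[-1]]) is not None:
            path.append(p)
        return path

    def leaf_set(self, node: str) -> frozenset[str]:
        """All leaf names descending from (or equal to) *node*."""
        if node not in self.parent:
            raise KeyError(f"unknown node: {node!r}")
        if node not in self._leafsets:
            # fill bottom-up in one pass over a postorder
            order = list(self.preorder())[::-1]
            for n in order:
                kids = self.children.get(n, [])
                if not kids:
                    self._leafsets[n] = frozenset([n])
                else:
                    s: set[str] = set()
                    for k in kids:
                        s |= self._leafsets[k]
                    self._leafsets[n] = frozenset(s)
        return self._leafsets[node]

    def is_ancestor_or_equal(self, anc: str, node: str) -> bool:
        return anc in self.path_to_root(node)

    # -- serialization ------------------------------------------------------

    def to_newick(self) -> str:
        def rec(node: str) -> str:
            kids = self.children.get(node, [])
            if not kids:
                return node
            return "(" + ",".join(rec(k) for k in kids) + ")" + node

        return rec(self.root) + ";"


def _phylogeny_from_dendropy(tree: dendropy.Tree) -> Phylogeny:
    """Convert a rooted dendropy tree, assigning N1..Nk preorder labels where
    internal labels are missing."""
    parent: dict[str, str | None] = {}
    children: dict[str, list[str]] = {}
    counter = 0
    names: dict[int, str] = {}
    seen: set[str] = set()

    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            name = nd.taxon.label if nd.taxon else nd.label
            if not name:
                raise FormatError("leaf without a name in newick")
        else:
            name = nd.label
            if not name:
                counter += 1
                name = f"N{counter}"
                while name in seen:
                    counter += 1
                    name = f"N{counter}"
        if name in seen:
            raise FormatError(f"duplicate node name in newick: {name!r}")
        seen.add(name)
        names[id(nd)] = name
        p = nd.parent_node
        parent[name] = names[id(p)] if p is not None else None
        children[name] = []
        if p is not None:
            children[names[id(p)]].append(name)

    root = next(n for n, p in parent.items() if p is None)
    return Phylogeny(root=root, parent=parent, children=children)


def phylogeny_from_newick_string(newick: str,
                                 outgroup: str | None = None) -> Phylogeny:
    """Parse a newick string (same contract as :func:`read_newick`)."""
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".nwk", delete=False) as fh:
        fh.write(newick)
        tmp = fh.name
    try:
        return read_newick(tmp, outgroup=outgroup)
    finally:
        Path(tmp).unlink(missing_ok=True)


def read_newick(path: str | Path, outgroup: str | None = None) -> Phylogeny:
    """Read a single-tree newick file into a rooted :class:`Phylogeny`.

    A basal polytomy is interpreted as an unrooted tree: it is an error unless
    *outgroup* names a leaf, in which case the tree is rooted on the branch
    leading to that leaf. If *outgroup* is given, rooting on its branch is
    performed regardless of the input's rooting state.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except dendropy.utility.error.DataParseError as exc:
        raise FormatError(f"{path}: leaf names not unique or malformed "
                          f"newick ({exc})") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise FormatError(f"leaf names not unique: {dupes}")

    if outgroup is not None:
        og_node = None
        for lf in tree.leaf_node_iter():
            if lf.taxon and lf.taxon.label == outgroup:
                og_node = lf
                break
        if og_node is None:
            raise FormatError(f"outgroup {outgroup!r} not found among leaves")
        tree.reroot_at_edge(og_node.edge, update_bipartitions=False)
    elif len(tree.seed_node.child_nodes()) > 2:
        raise FormatError(
            "tree appears unrooted (basal polytomy); supply an outgroup leaf"
        )
    return _phylogeny_from_dendropy(tree)


def write_newick(tree: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Orthogroup table
# ---------------------------------------------------------------------------


@dataclass
class OrthogroupTable:
    """Orthogroup membership: orthogroup -> species -> list of gene IDs.

    ``species`` is the ordered roster from the file header; absent species are
    represented by empty lists so copy counts are always defined.
    """

    species: list[str]
    groups: dict[str, dict[str, list[str]]]

    def __post_init__(self) -> None:
        roster = set(self.species)
        for og, per_sp in self.groups.items():
            extra = set(per_sp) - roster
            if extra:
                raise ValueError(f"{og}: species not in roster: {sorted(extra)}")
            for sp in self.species:
                per_sp.setdefault(sp, [])
            for sp, genes in per_sp.items():
                if len(genes) != len(set(genes)):
                    raise ValueError(f"{og}/{sp}: duplicate gene IDs")

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.groups)

    def copy_count(self, og: str, species: str) -> int:
        return len(self.groups[og][species])

    def presence_set(self, og: str) -> frozenset[str]:
        """Species with at least one gene copy in *og*."""
        return frozenset(sp for sp in self.species if self.groups[og][sp])

    def gene_to_orthogroup(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for og, per_sp in self.groups.items():
            for genes in per_sp.values():
                for g in genes:
                    out[g] = og
        return out

    def subset(self, orthogroups: Iterable[str]) -> "OrthogroupTable":
        keep = list(orthogroups)
        missing = [og for og in keep if og not in self.groups]
        if missing:
            raise KeyError(f"unknown orthogroups: {missing}")
        return OrthogroupTable(
            species=list(self.species),
            groups={og: {sp: list(v) for sp, v in self.groups[og].items()}
                    for og in keep},
        )


def read_orthogroups(path: str | Path) -> OrthogroupTable:
    """Parse an OrthoFinder-style ``Orthogroups.tsv``.

    Header is ``Orthogroup<TAB>sp1<TAB>...``; cells are ", "-separated gene
    lists, possibly empty. Duplicated orthogroup IDs and ragged rows are hard
    errors.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: header must list at least one species")
    species = header[1:]
    ncol = len(header)
    groups: dict[str, dict[str, list[str]]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != ncol:
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(cells)} columns, "
                f"expected {ncol})"
            )
        og = cells[0]
        if og in groups:
            raise FormatError(f"{path}:{lineno}: duplicated orthogroup ID {og!r}")
        groups[og] = {
            sp: ([g.strip() for g in cell.split(",") if g.strip()]
                 if cell.strip() else [])
            for sp, cell in zip(species, cells[1:])
        }
    return OrthogroupTable(species=species, groups=groups)


def write_orthogroups(table: OrthogroupTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Orthogroup\t" + "\t".join(table.species) + "\n")
        for og in table.orthogroup_ids:
            cells = [", ".join(table.groups[og][sp]) for sp in table.species]
            fh.write(og + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Homology hits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HitRecord:
    """One filtered homology-search hit with subject taxonomy attached."""

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    query_coverage_pct: float
    subject_coverage_pct: float
    subject_taxon_class: str

    def __post_init__(self) -> None:
        for name in ("percent_identity", "query_coverage_pct",
                     "subject_coverage_pct"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"evalue={self.evalue} is negative")
        if self.subject_taxon_class not in TAXON_CLASSES:
            raise ValueError(
                f"unknown taxon class {self.subject_taxon_class!r}; "
                f"expected one of {TAXON_CLASSES}"
            )


# BLAST outfmt 6 default column order; 14-column files append qlen, slen.
_OUTFMT6 = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
_OUTFMT6_14 = _OUTFMT6 + ["qlen", "slen"]


def _span_cov(a: float, b: float, length: float) -> float:
    return (abs(b - a) + 1.0) / length * 100.0


def read_taxon_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping subject ID to taxon class."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns")
        sid, cls = parts
        if cls not in TAXON_CLASSES:
            raise FormatError(
                f"{path}:{lineno}: unknown taxon class {cls!r}")
        out[sid] = cls
    return out


def read_hits(
    path: str | Path,
    taxon_map: Mapping[str, str],
    missing_taxon: str = "drop",
) -> tuple[list[HitRecord], int]:
    """Read a BLAST outfmt-6-like TSV into :class:`HitRecord` objects.

    Accepts headerless 12- or 14-column files (14-column files carry
    ``qlen``/``slen``, from which coverage is computed as
    ``(aligned span / length) * 100``) or files with a header naming at least
    ``qseqid sseqid pident evalue`` plus either ``qcovs``/``scovs`` or the
    coordinate+length columns.

    ``missing_taxon`` is ``"drop"`` (exclude the record, count it) or
    ``"error"``. Returns ``(records, n_dropped)``.
    """
    if missing_taxon not in ("drop", "error"):
        raise ValueError("missing_taxon must be 'drop' or 'error'")
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        return [], 0

    first = lines[0].split("\t")
    if "qseqid" in first:  # header present
        cols = first
        body = lines[1:]
        start_line = 2
    else:
        cols = _OUTFMT6 if len(first) == 12 else _OUTFMT6_14
        if len(first) not in (12, 14):
            raise FormatError(
                f"{path}: headerless hit table must have 12 or 14 columns, "
                f"found {len(first)}")
        body = lines
        start_line = 1

    idx = {c: i for i, c in enumerate(cols)}
    for req in ("qseqid", "sseqid", "pident", "evalue"):
        if req not in idx:
            raise FormatError(f"{path}: missing required column {req!r}")
    direct_cov = "qcovs" in idx and "scovs" in idx
    coord_cov = all(c in idx for c in ("qstart", "qend", "qlen",
                                       "sstart", "send", "slen"))
    if not direct_cov and not coord_cov:
        raise FormatError(
            f"{path}: need qcovs/scovs or qstart,qend,qlen,sstart,send,slen")

    records: list[HitRecord] = []
    dropped = 0
    for lineno, line in enumerate(body, start=start_line):
        cells = line.split("\t")
        if len(cells) != len(cols):
            raise FormatError(f"{path}:{lineno}: expected {len(cols)} columns")

        def num(col: str) -> float:
            try:
                return float(cells[idx[col]])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: malformed numeric field "
                    f"{col}={cells[idx[col]]!r}") from None

        sid = cells[idx["sseqid"]]
        if sid not in taxon_map:
            if missing_taxon == "error":
                raise FormatError(
                    f"{path}:{lineno}: subject {sid!r} absent from taxon map")
            dropped += 1
            continue
        if direct_cov:
            qcov, scov = num("qcovs"), num("scovs")
        else:
            qcov = _span_cov(num("qstart"), num("qend"), num("qlen"))
            scov = _span_cov(num("sstart"), num("send"), num("slen"))
        records.append(HitRecord(
            query_id=cells[idx["qseqid"]],
            subject_id=sid,
            percent_identity=num("pident"),
            evalue=num("evalue"),
            query_coverage_pct=qcov,
            subject_coverage_pct=scov,
            subject_taxon_class=taxon_map[sid],
        ))
    return records, dropped


# ---------------------------------------------------------------------------
# Domain annotations
# ---------------------------------------------------------------------------


@dataclass
class DomainAnnotation:
    """Per-gene protein-domain calls: gene -> [(accession, e-value), ...].

    An absent gene or an empty list both mean "no domain detected".
    """

    domains: dict[str, list[tuple[str, float]]]

    def __post_init__(self) -> None:
        for gene, hits in self.domains.items():
            for acc, ev in hits:
                if ev < 0:
                    raise ValueError(f"{gene}/{acc}: negative e-value {ev}")

    def for_gene(self, gene: str, max_evalue: float = 1e-3) -> list[str]:
        return [acc for acc, ev in self.domains.get(gene, [])
                if ev <= max_evalue]

    def for_genes(self, genes: Iterable[str],
                  max_evalue: float = 1e-3) -> list[str]:
        out: list[str] = []
        for g in genes:
            out.extend(self.for_gene(g, max_evalue))
        return sorted(set(out))


def read_domains(path: str | Path) -> DomainAnnotation:
    """Read a 3-column TSV: gene_id, domain accession, e-value."""
    domains: dict[str, list[tuple[str, float]]] = {}
    for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns")
        gene, acc, ev_s = parts
        try:
            ev = float(ev_s)
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: malformed e-value {ev_s!r}") from None
        domains.setdefault(gene, []).append((acc, ev))
    return DomainAnnotation(domains=domains)


# ---------------------------------------------------------------------------
# Gene models (GFF3)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """One gene locus with per-transcript exon counts.

    Coordinates are 1-based inclusive. The gene-level intron count is taken
    from the longest transcript (``exon_count - 1``).
    """

    species: str
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exon_counts: tuple[int, ...]  # one entry per transcript
    transcript_lengths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if any(e < 1 for e in self.exon_counts):
            raise ValueError(f"{self.gene_id}: exon count < 1")

    @property
    def intron_count(self) -> int:
        """Intron count of the longest transcript (convention; flagged in
        outputs)."""
        if not self.exon_counts:
            raise ValueError(f"{self.gene_id}: no transcripts")
        if self.transcript_lengths and \
                len(self.transcript_lengths) == len(self.exon_counts):
            best = max(range(len(self.exon_counts)),
                       key=lambda i: (self.transcript_lengths[i],
                                      self.exon_counts[i]))
        else:
            best = max(range(len(self.exon_counts)),
                       key=lambda i: self.exon_counts[i])
        return self.exon_counts[best] - 1


def read_gff(path: str | Path, species: str | None = None) -> list[GeneModel]:
    """Read gene/mRNA/exon features from a GFF3 file into gene models.

    *species* defaults to the file's stem. Exons falling outside their parent
    gene's span raise a warning, not an error.
    """
    import gffutils

    sp = species if species is not None else Path(path).stem
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        exon_counts: list[int] = []
        tx_lengths: list[int] = []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = list(db.children(mrna, featuretype="exon"))
            if not exons:
                continue
            for ex in exons:
                if ex.start < gene.start or ex.end > gene.end:
                    warnings.warn(
                        f"{gene.id}: exon {ex.id} outside gene span",
                        stacklevel=2)
            exon_counts.append(len(exons))
            tx_lengths.append(sum(ex.end - ex.start + 1 for ex in exons))
        if not exon_counts:  # gene without annotated mRNA: single-exon model
            exon_counts, tx_lengths = [1], [gene.end - gene.start + 1]
        models.append(GeneModel(
            species=sp,
            gene_id=gene.id,
            chromosome=gene.seqid,
            start=gene.start,
            end=gene.end,
            strand=gene.strand if gene.strand in ("+", "-") else "+",
            exon_counts=tuple(exon_counts),
            transcript_lengths=tuple(tx_lengths),
        ))
    return models


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x condition abundance matrix.

    Replicate samples for the same (tissue, lifestage) pair are averaged into
    a single column labelled ``tissue|lifestage``.
    """

    values: pd.DataFrame  # genes x conditions
    conditions: dict[str, tuple[str, str]]  # column -> (tissue, lifestage)


def read_expression(
    path: str | Path,
    sample_meta: Mapping[str, tuple[str, str]],
) -> ExpressionMatrix:
    """Read a gene x sample TSV and average replicates per (tissue, lifestage).

    ``sample_meta`` maps each sample column to its (tissue, lifestage) pair.
    Negative abundances are a hard error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    unknown = [c for c in df.columns if c not in sample_meta]
    if unknown:
        raise FormatError(f"{path}: samples without metadata: {unknown}")
    if (df.to_numpy() < 0).any():
        bad = df[(df < 0).any(axis=1)].index.tolist()
        raise FormatError(f"{path}: negative abundance for genes {bad}")
    by_cond: dict[str, list[str]] = {}
    conditions: dict[str, tuple[str, str]] = {}
    for col in df.columns:
        tissue, stage = sample_meta[col]
        key = f"{tissue}|{stage}"
        by_cond.setdefault(key, []).append(col)
        conditions[key] = (tissue, stage)
    out = pd.DataFrame(
        {key: df[cols].mean(axis=1) for key, cols in by_cond.items()},
        index=df.index,
    )
    return ExpressionMatrix(values=out, conditions=conditions)
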