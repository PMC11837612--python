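"""End-to-end orchestration: ingest -> gains -> classify -> copy statistics.

A run is driven by a flat key=value config file (``#`` comments allowed; CLI
flags override file values). Every stage writes plain TSV outputs plus a JSON
run report whose counts must reconcile: retained + excluded = total
orthogroups, per-node gains sum to the retained count, and per-node origin
labels sum to that node's gain count. A reconciliation failure is an
invariant violation, not an input error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .copy_stats import copy_matrix, dunn_flag, retention
from .gain_mapping import assign_gains, orthogroups_at
from .io_formats import (
    DomainAnnotation,
    read_domains,
    read_hits,
    read_newick,
    read_orthogroups,
    read_taxon_map,
)
from .origin_classify import classify_origin, filter_hits, summarize_modes

__all__ = ["RunConfig", "RunReport", "PipelineInvariantError",
           "read_run_config", "run_pipeline"]

log = logging.getLogger("genovmap")


class PipelineInvariantError(RuntimeError):
    """A cross-stage count failed to reconcile."""


@dataclass
class RunConfig:
    """All inputs and thresholds of a pipeline run. Unknown config keys are
    rejected so typos cannot silently fall back to defaults."""

    tree: str
    orthogroups: str
    out_dir: str
    hits_metazoa: str | None = None
    hits_nonmetazoa: str | None = None
    domains: str | None = None
    taxon_map: str | None = None
    node: str | None = None          # focal gain node for the copy screen
    min_species: int = 3
    max_evalue: float = 1e-5
    min_identity: float = 25.0
    min_qcov: float = 60.0
    min_scov: float = 60.0
    domain_evalue: float = 1e-3
    retention_threshold: float = 0.75
    alpha: float = 0.05
    adjust: str = "bh"
    seed: int = 0

    _FLOATS = ("max_evalue", "min_identity", "min_qcov", "min_scov",
               "domain_evalue", "retention_threshold", "alpha")
    _INTS = ("min_species", "seed")


@dataclass
class RunReport:
    version: str
    seed: int
    thresholds: dict[str, Any]
    stage_counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def read_run_config(path: str | Path, **overrides: Any) -> RunConfig:
    """Parse a flat ``key = value`` config file; *overrides* win."""
    values: dict[str, Any] = {}
    for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip().strip('"')
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for k in RunConfig._FLOATS:
        if k in values:
            values[k] = float(values[k])
    for k in RunConfig._INTS:
        if k in values:
            values[k] = int(values[k])
    return RunConfig(**values)


def _setup_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s")
    log.setLevel(logging.INFO)
    log.handlers.clear()
    for handler in (logging.StreamHandler(),
                    logging.FileHandler(out_dir / "run.log", mode="w")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute ingest -> gain mapping -> origin classification -> copy screen.

    Classification runs only when hit tables and a taxon map are configured;
    the copy screen runs on the configured focal node (default: the non-root
    internal node with the most gains).
    """
    out = Path(config.out_dir)
    _setup_logging(out)
    thresholds = {k: getattr(config, k)
                  for k in (*RunConfig._FLOATS, *RunConfig._INTS, "adjust")}
    report = RunReport(version=__version__, seed=config.seed,
                       thresholds=thresholds)

    # -- ingest ---------------------------------------------------------
    tree = read_newick(config.tree)
    table = read_orthogroups(config.orthogroups)
    if not table.orthogroup_ids:
        raise ValueError(f"{config.orthogroups}: no orthogroups")
    log.info("ingest: %d orthogroups, %d species, %d tree leaves",
             len(table.orthogroup_ids), len(table.species),
             len(tree.leaves))
    report.stage_counts["orthogroups_total"] = len(table.orthogroup_ids)

    # -- gains ----------------------------------------------------------
    gains = assign_gains(tree, table, min_species=config.min_species)
    n_retained = len(gains.assignments)
    report.stage_counts["orthogroups_retained"] = n_retained
    report.stage_counts["orthogroups_excluded"] = len(gains.excluded)
    if n_retained + len(gains.excluded) != len(table.orthogroup_ids):
        raise PipelineInvariantError(
            "gains: retained + excluded != total orthogroups")
    if sum(gains.node_counts.values()) != n_retained:
        raise PipelineInvariantError(
            "gains: per-node counts do not sum to retained orthogroups")
    gm = pd.DataFrame(sorted(gains.assignments.items()),
                      columns=["orthogroup", "gain_node"])
    gm.to_csv(out / "gain_map.tsv", sep="\t", index=False)
    nc = pd.DataFrame(sorted(gains.node_counts.items()),
                      columns=["node", "n_gained"])
    nc.to_csv(out / "node_counts.tsv", sep="\t", index=False)
    report.outputs["gain_map"] = str(out / "gain_map.tsv")
    report.outputs["node_counts"] = str(out / "node_counts.tsv")
    log.info("gains: %d retained (%d excluded) over %d nodes",
             n_retained, len(gains.excluded), len(gains.node_counts))

    # focal node: configured, else the busiest non-root internal node
    node = config.node
    if node is None:
        candidates = [(n, c) for n, c in gains.node_counts.items()
                      if n != tree.root and not tree.is_leaf(n)]
        node = max(candidates, key=lambda x: (x[1], x[0]))[0] \
            if candidates else tree.root
    elif node not in tree.parent:
        raise ValueError(f"focal node {node!r} not in tree")
    node_ogs = orthogroups_at(gains, node, tree)
    report.stage_counts["orthogroups_at_focal_node"] = len(node_ogs)
    log.info("focal node %s: %d orthogroups", node, len(node_ogs))

    # -- classify -------------------------------------------------------
    if config.hits_metazoa and config.hits_nonmetazoa and config.taxon_map:
        taxon_map = read_taxon_map(config.taxon_map)
        met_raw, _ = read_hits(config.hits_metazoa, taxon_map)
        non_raw, _ = read_hits(config.hits_nonmetazoa, taxon_map)
        fkw = dict(max_evalue=config.max_evalue,
                   min_identity=config.min_identity,
                   min_qcov=config.min_qcov, min_scov=config.min_scov)
        met = filter_hits(met_raw, **fkw)
        non = filter_hits(non_raw, **fkw)
        domains = (read_domains(config.domains) if config.domains
                   else DomainAnnotation(domains={}))
        calls = [
            classify_origin(
                og,
                [g for sp in table.species for g in table.groups[og][sp]],
                domains, met, non, domain_evalue=config.domain_evalue)
            for og in gains.assignments
        ]
        pd.DataFrame(
            [(c.orthogroup_id, c.label, c.n_metazoan_hits,
              c.n_nonmetazoan_hits, ";".join(c.domain_accessions),
              c.n_partial_hits) for c in calls],
            columns=["orthogroup", "label", "n_metazoan_hits",
                     "n_nonmetazoan_hits", "domains", "n_partial_hits"],
        ).to_csv(out / "origin_calls.tsv", sep="\t", index=False)
        summary = summarize_modes(calls, gains)
        summary.to_csv(out / "mode_summary.tsv", sep="\t")
        report.outputs["origin_calls"] = str(out / "origin_calls.tsv")
        report.outputs["mode_summary"] = str(out / "mode_summary.tsv")
        report.stage_counts["orthogroups_classified"] = len(calls)
        if len(calls) != n_retained:
            raise PipelineInvariantError(
                "classify: classified != retained orthogroups")
        for nd, row in summary.iterrows():
            if int(row["total"]) != gains.node_counts.get(nd, 0):
                raise PipelineInvariantError(
                    f"classify: label counts at {nd} do not sum to its "
                    "gain count")
        log.info("classify: %d calls (%s)", len(calls),
                 ", ".join(f"{k}={int(summary[k].sum())}"
                           for k in summary.columns if k != "total"))

    # -- copy screen ----------------------------------------------------
    focal_species = sorted(tree.leaf_set(node))
    if node_ogs and len(node_ogs) >= 2:
        mat = copy_matrix(table.subset(node_ogs), focal_species)
        mat.to_csv(out / "copy_matrix.tsv", sep="\t")
        ret = retention(mat, threshold=config.retention_threshold)
        ret.to_csv(out / "retention.tsv", sep="\t")
        outliers = dunn_flag(mat, alpha=config.alpha, adjust=config.adjust)
        outliers.dunn.to_csv(out / "outliers.tsv", sep="\t")
        report.outputs.update({
            "copy_matrix": str(out / "copy_matrix.tsv"),
            "retention": str(out / "retention.tsv"),
            "outliers": str(out / "outliers.tsv"),
        })
        report.stage_counts["orthogroups_retained_75"] = \
            int(ret["retained"].sum())
        report.stage_counts["orthogroups_flagged_expanded"] = \
            len(outliers.flagged)
        log.info("copystats: grand mean %.4f, %d retained at %.0f%%, "
                 "%d flagged", outliers.grand_mean,
                 int(ret["retained"].sum()),
                 100 * config.retention_threshold, len(outliers.flagged))

    (out / "run_report.json").write_text(report.to_json() + "\n",
                                         encoding="utf-8")
    report.outputs["run_report"] = str(out / "run_report.json")
    return report
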