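"""End-to-end orchestration: read -> enrich -> select -> score -> aggregate.

A single :class:`RunConfig` (YAML on disk) names the inputs — one or two
DE contrast tables, a GMT file, an optional hierarchy, a directory of
per-term STRING edge tables and a category map — plus the thresholds
(q < 0.05, FDR < 0.05, combined score >= 0.900, max 2000-gene terms, top
10% by default).  :func:`run_pipeline` executes the stages in order and
writes five TSV report tables plus a JSON manifest recording the config,
stage counts, exclusions and output checksums.  Reruns of the same
config are byte-identical.

Enrichment and term selection are driven by the primary contrast; the
fold-change and weight summaries are produced for every contrast so two
analyses (e.g. control-vs-insult and insult-vs-treatment) can be read
side by side.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .aggregate import (
    load_category_map,
    resolve_gene_weights,
    shared_deg_overlap,
    structure_fc_summary,
    structure_weighted_summary,
    top_fraction,
)
from .enrich import enrichment_frame, fisher_overrepresentation, select_terms
from .io import (
    ParameterError,
    file_sha256,
    read_deg_table,
    read_gmt,
    read_hierarchy,
    read_string_interactions,
    write_deg_table,
    write_gmt,
    write_hierarchy,
    write_manifest,
    write_string_interactions,
)
from .scoring import GeneWeight, score_network
from .synth import StudyData

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "write_study", "OUTPUT_TABLES"]

#: report tables written by every successful run
OUTPUT_TABLES = (
    "enrichment.tsv",
    "node_metrics.tsv",
    "structure_summary.tsv",
    "shared_degs.tsv",
    "top_genes.tsv",
)

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; the message is prefixed with the stage name."""


def sanitize_term_id(term_id: str) -> str:
    """Filesystem-safe version of a term id (GO:0005743 -> GO_0005743)."""
    return term_id.replace(":", "_").replace("/", "_")


@dataclass
class RunConfig:
    """All inputs and parameters of one pipeline run."""

    deg_tables: dict[str, str]  # contrast label -> path
    gmt: str
    network_dir: str
    category_map: str
    out_dir: str
    hierarchy: str | None = None
    primary_contrast: str | None = None  # default: first label
    q_threshold: float = 0.05
    fdr_threshold: float = 0.05
    max_term_size: int = 2000
    score_threshold: float = 0.9
    top_fraction: float = 0.1
    fisher_alternative: str = "two-sided"
    betweenness_normalized: bool = False
    whole_graph_v: bool = False
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
        cfg = cls(**kwargs)
        # resolve relative paths against the config file's directory
        base = path.parent
        cfg.deg_tables = {k: str(base / v) for k, v in cfg.deg_tables.items()}
        cfg.gmt = str(base / cfg.gmt)
        cfg.network_dir = str(base / cfg.network_dir)
        cfg.category_map = str(base / cfg.category_map)
        cfg.out_dir = str(base / cfg.out_dir)
        if cfg.hierarchy is not None:
            cfg.hierarchy = str(base / cfg.hierarchy)
        return cfg

    def validate(self) -> None:
        if not self.deg_tables:
            raise ParameterError("no DE tables configured")
        for label, p in self.deg_tables.items():
            if not Path(p).is_file():
                raise ParameterError(f"DE table {label!r} not found: {p}")
        for p in (self.gmt, self.category_map):
            if not Path(p).is_file():
                raise ParameterError(f"input file not found: {p}")
        if self.hierarchy is not None and not Path(self.hierarchy).is_file():
            raise ParameterError(f"hierarchy file not found: {self.hierarchy}")
        if not Path(self.network_dir).is_dir():
            raise ParameterError(f"network directory not found: {self.network_dir}")
        if not 0.0 < self.q_threshold <= 1.0:
            raise ParameterError(f"q_threshold {self.q_threshold} outside (0, 1]")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ParameterError(f"top_fraction {self.top_fraction} outside (0, 1]")

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the output directory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "netprio",
        "version": __version__,
        "config": config.snapshot(),
        "weight_formula": "W = BC * CCe * log2(NC) * CCo^2 - log2(V * AVP)",
        "status": "running",
        "counts": {},
        "exclusions": {},
        "checksums": {},
    }
    stage = "configure"
    try:
        config.validate()
        primary = config.primary_contrast or next(iter(config.deg_tables))
        if primary not in config.deg_tables:
            raise ParameterError(f"primary contrast {primary!r} has no DE table")

        stage = "read"
        universe_table = read_deg_table(config.deg_tables[primary], q_threshold=None)
        universe = set(universe_table["gene"])
        degs = {
            label: read_deg_table(path, q_threshold=config.q_threshold)
            for label, path in config.deg_tables.items()
        }
        terms = read_gmt(config.gmt)
        if config.hierarchy:
            read_hierarchy(config.hierarchy, terms)
        cmap = load_category_map(config.category_map)
        manifest["counts"]["universe"] = len(universe)
        manifest["counts"]["degs"] = {k: len(v) for k, v in degs.items()}
        manifest["counts"]["terms"] = len(terms)

        stage = "enrich"
        results = fisher_overrepresentation(
            set(degs[primary]["gene"]),
            universe,
            terms,
            alternative=config.fisher_alternative,
        )

        stage = "select"
        retained, exclusions = select_terms(
            results, terms, config.fdr_threshold, config.max_term_size
        )
        manifest["counts"]["terms_tested"] = len(results)
        manifest["counts"]["terms_retained"] = len(retained)
        manifest["exclusions"]["terms"] = exclusions
        enrich_df = enrichment_frame(results, retained, exclusions)

        stage = "score"
        metric_frames: list[pd.DataFrame] = []
        weights: list[GeneWeight] = []
        for term_id in retained:
            net_path = Path(config.network_dir) / f"{sanitize_term_id(term_id)}.tsv"
            if not net_path.is_file():
                raise ParameterError(f"network file missing for term {term_id}: {net_path}")
            edges = read_string_interactions(net_path, config.score_threshold)
            frame = score_network(
                edges,
                term_id,
                betweenness_normalized=config.betweenness_normalized,
                whole_graph_v=config.whole_graph_v,
            )
            metric_frames.append(frame)
            for rec in frame.itertuples(index=False):
                weights.append(
                    GeneWeight(
                        gene=rec.gene,
                        term_id=term_id,
                        w=rec.w,
                        substituted=frozenset(
                            rec.substituted.split(",") if rec.substituted else []
                        ),
                    )
                )
        metrics_df = (
            pd.concat(metric_frames, ignore_index=True)
            if metric_frames
            else pd.DataFrame(
                columns=[
                    "term_id", "gene", "bc", "cce", "nc", "cco",
                    "avp", "v", "component_id", "substituted", "w",
                ]
            )
        )
        manifest["counts"]["nodes_scored"] = len(metrics_df)

        stage = "aggregate"
        retained_terms = [t for t in terms if t.term_id in set(retained)]
        retained_cmap = {
            cat: [t for t in tids if t in set(retained)]
            for cat, tids in cmap.items()
        }
        retained_cmap = {cat: tids for cat, tids in retained_cmap.items() if tids}
        summary_rows: list[pd.DataFrame] = []
        shared_rows: list[pd.DataFrame] = []
        gene_struct_rows: list[pd.DataFrame] = []
        top_rows: list[pd.DataFrame] = []
        for label in sorted(degs):
            deg_tab = degs[label]
            deg_weights = [
                gw for gw in weights if gw.gene in set(deg_tab["gene"])
            ]
            resolved = resolve_gene_weights(deg_weights, retained_cmap)
            fc_sum = structure_fc_summary(deg_tab, retained_cmap, retained_terms)
            w_sum = structure_weighted_summary(deg_tab, resolved)
            merged = fc_sum.merge(
                w_sum, on="category", suffixes=("_annotated", "_weighted")
            )
            merged.insert(0, "contrast", label)
            summary_rows.append(merged)

            mat, gene_table = shared_deg_overlap(retained_cmap, retained_terms, deg_tab)
            long = (
                mat.stack()
                .rename_axis(["category_a", "category_b"])
                .reset_index(name="shared_degs")
            )
            long.insert(0, "contrast", label)
            shared_rows.append(long)
            gene_table.insert(0, "contrast", label)
            gene_struct_rows.append(gene_table)

            top = top_fraction(resolved, deg_tab, config.top_fraction)
            top.insert(0, "contrast", label)
            top_rows.append(top)

        stage = "report"
        _write_tsv(enrich_df, out_dir / "enrichment.tsv")
        _write_tsv(metrics_df, out_dir / "node_metrics.tsv")
        _write_tsv(pd.concat(summary_rows, ignore_index=True), out_dir / "structure_summary.tsv")
        _write_tsv(pd.concat(shared_rows, ignore_index=True), out_dir / "shared_degs.tsv")
        _write_tsv(
            pd.concat(gene_struct_rows, ignore_index=True),
            out_dir / "gene_structures.tsv",
        )
        _write_tsv(pd.concat(top_rows, ignore_index=True), out_dir / "top_genes.tsv")

        manifest["status"] = "ok"
        for name in (*OUTPUT_TABLES, "gene_structures.tsv"):
            manifest["checksums"][name] = file_sha256(out_dir / name)
        write_manifest(manifest, out_dir / "manifest.json")
        return out_dir
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        write_manifest(manifest, out_dir / "manifest.json")
        raise PipelineError(f"[{stage}] {exc}") from exc


def write_study(study: StudyData, out_dir: str | Path) -> Path:
    """Write a synthetic study to disk plus a ready-to-run config YAML.

    Returns the path of the written config file.  The layout is
    ``deg_<label>.tsv``, ``terms.gmt``, ``hierarchy.tsv``,
    ``networks/<term>.tsv``, ``category_map.yaml``, ``truth.json`` and
    ``config.yaml``; outputs of a run go to ``results/``.
    """
    out_dir = Path(out_dir)
    (out_dir / "networks").mkdir(parents=True, exist_ok=True)

    deg_paths: dict[str, str] = {}
    for label, table in study.deg_tables.items():
        name = f"deg_{label}.tsv"
        canonical = table.rename(
            columns={"log2FoldChange": "log2fc", "padj": "qvalue"}
        )
        write_deg_table(canonical, out_dir / name)
        deg_paths[label] = name

    write_gmt(study.terms, out_dir / "terms.gmt")
    write_hierarchy(study.hierarchy, out_dir / "hierarchy.tsv")
    for term_id in sorted(study.networks):
        write_string_interactions(
            study.networks[term_id],
            out_dir / "networks" / f"{sanitize_term_id(term_id)}.tsv",
        )
    with open(out_dir / "category_map.yaml", "w") as fh:
        yaml.safe_dump(study.category_map, fh, sort_keys=True)

    truth = {
        "seed": study.truth.seed,
        "deg_genes": sorted(study.truth.deg_genes),
        "enriched_terms": sorted(study.truth.enriched_terms),
        "planted_hubs": {
            t: sorted(h) for t, h in sorted(study.truth.planted_hubs.items())
        },
    }
    write_manifest(truth, out_dir / "truth.json")

    config = {
        "deg_tables": deg_paths,
        "primary_contrast": study.primary_contrast,
        "gmt": "terms.gmt",
        "hierarchy": "hierarchy.tsv",
        "network_dir": "networks",
        "category_map": "category_map.yaml",
        "out_dir": "results",
        "seed": study.truth.seed,
    }
    cfg_path = out_dir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return cfg_path
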