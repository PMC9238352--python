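"""End-to-end orchestration: stats -> DEGs -> pathway scoring -> KO-ROC -> Venn.

A run is driven by one configuration (YAML on disk or an in-memory
:class:`PipelineConfig`), is fully seeded, and materializes every stage
output plus a manifest with checksums and a run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Any

import yaml

from . import deg_select, expression_stats, ko_roc_eval, pathway_model, spia_core
from . import synthetic_data, venn_core
from .errors import ValidationError

logger = logging.getLogger(__name__)

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulate`` (a parameter mapping for the synthetic
    generator) or the triple (``expression``, ``metadata``, ``kgml_dir``)
    must be given.
    """

    ko_gene: str = "G0001"
    contrasts: tuple[str, ...] = ("A", "B", "C")
    n_boot: int = spia_core.DEFAULT_N_BOOT
    seed: int = 0
    expression: str | None = None
    metadata: str | None = None
    kgml_dir: str | None = None
    simulate: dict[str, Any] | None = None
    weight_table: dict[str, int] = field(
        default_factory=lambda: dict(pathway_model.DEFAULT_WEIGHT_TABLE)
    )
    probe_collapse: str = "max_mean"

    def __post_init__(self) -> None:
        has_paths = all(
            v is not None for v in (self.expression, self.metadata, self.kgml_dir)
        )
        has_sim = self.simulate is not None
        if has_paths == has_sim:
            raise ValidationError(
                "config must provide either the real data paths "
                "(expression, metadata, kgml_dir) or a simulate block, not both"
            )
        for label in self.contrasts:
            if label not in expression_stats.DEFAULT_CONTRASTS:
                raise ValidationError(f"unknown contrast label {label!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "contrasts" in raw:
            raw["contrasts"] = tuple(raw["contrasts"])
        return cls(**raw)


@dataclass
class RunArtifacts:
    """Produced files plus the run log."""

    out_dir: Path
    manifest: dict[str, str]  # relative path -> sha256
    log: dict[str, Any]
    roc_summaries: dict[str, ko_roc_eval.RocSummary]
    spia_tables: dict[str, list[spia_core.SpiaResult]]
    deg_sets: dict[str, deg_select.DegSet]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _round_half_away(value: float, decimals: int = 1) -> float:
    quant = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(quant, rounding=ROUND_HALF_UP))


def format_deg_pct(nde: int, psize: int) -> str:
    """Render the 'DEGs (%)' cell, e.g. 43 of 69 -> ``43 (62.3)``."""
    pct = 100.0 * nde / psize if psize else 0.0
    return f"{nde} ({_round_half_away(pct, 1):.1f})"


def _stars(p: float) -> str:
    for cutoff, mark in STAR_THRESHOLDS:
        if p < cutoff:
            return mark
    return ""


def format_results_table(rows: list[spia_core.SpiaResult]) -> str:
    """Text table mirroring the printed per-pathway report.

    Columns: ID, Pathway Name, Status, pSize, DEGs (%), pGFdr (3 significant
    digits, scientific) plus significance stars; rows sorted ascending by
    pGFdr.
    """
    header = ["ID", "Pathway Name", "Status", "pSize", "DEGs (%)", "pGFdr", ""]
    body = []
    for r in sorted(rows, key=lambda r: (r.p_g_fdr, r.pathway_id)):
        body.append([
            r.pathway_id,
            r.name,
            r.status,
            str(r.psize),
            format_deg_pct(r.nde, r.psize),
            f"{r.p_g_fdr:.2E}",
            _stars(r.p_g_fdr),
        ])
    widths = [
        max(len(row[i]) for row in [header] + body) for i in range(len(header))
    ]
    lines = ["\t".join(h.ljust(w) for h, w in zip(header, widths)).rstrip()]
    for row in body:
        lines.append("\t".join(c.ljust(w) for c, w in zip(row, widths)).rstrip())
    return "\n".join(lines) + "\n"


def _load_inputs(
    config: PipelineConfig, out_dir: Path
) -> tuple[
    pathway_model.PathwayCollection,
    expression_stats.ExpressionMatrix,
    synthetic_data.PlantedTruth | None,
]:
    if config.simulate is not None:
        params = synthetic_data.SimulationParams(
            **{**config.simulate, "ko_gene": config.ko_gene, "seed": config.seed}
        )
        collection, truth = synthetic_data.simulate_pathway_collection(params)
        values, metadata = synthetic_data.simulate_expression(
            params, collection, truth
        )
        sim_dir = out_dir / "simulated"
        sim_dir.mkdir(parents=True, exist_ok=True)
        synthetic_data.write_expression_tsv(values, sim_dir / "expression.tsv")
        synthetic_data.write_metadata_tsv(metadata, sim_dir / "metadata.tsv")
        synthetic_data.write_kgml_fixtures(collection, sim_dir / "kgml")
        synthetic_data.write_truth_json(truth, params, sim_dir / "truth.json")
        matrix = expression_stats.ExpressionMatrix(values=values, metadata=metadata)
        return collection, matrix, truth
    matrix = expression_stats.read_expression(config.expression, config.metadata)
    if matrix.values.index.duplicated().any():
        matrix.values = expression_stats.collapse_probes(
            matrix.values, rule=config.probe_collapse
        )
    collection = pathway_model.parse_kgml_directory(
        config.kgml_dir,
        weight_table=config.weight_table,
        gene_universe=matrix.genes,
    )
    return collection, matrix, None


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunArtifacts:
    """Execute every stage for every configured contrast.

    Per contrast: gene stats, edge scores, change-point threshold, DEG set,
    pathway scoring table and KO-ROC summary; across contrasts the Venn
    partition of the DEG sets.  Deterministic for a fixed config and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict[str, Any] = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "seed": config.seed,
        "warnings": [],
        "excluded_pathways": {},
    }

    collection, matrix, truth = _load_inputs(config, out_dir)
    net = pathway_model.merge_global_network(collection)
    if net.n_sign_conflicts:
        log["warnings"].append(
            f"global network: {net.n_sign_conflicts} sign conflicts resolved "
            "in favor of the first-listed pathway"
        )
    pathway_model.write_graph_summary_tsv(collection, out_dir / "pathways.tsv")
    pathway_model.write_edge_list_tsv(net, out_dir / "global_edges.tsv")

    roc_summaries: dict[str, ko_roc_eval.RocSummary] = {}
    spia_tables: dict[str, list[spia_core.SpiaResult]] = {}
    deg_sets: dict[str, deg_select.DegSet] = {}
    for label in config.contrasts:
        cdir = out_dir / f"contrast_{label}"
        cdir.mkdir(exist_ok=True)
        contrast = expression_stats.ContrastSpec.default(label)
        stats = expression_stats.compute_gene_stats(matrix, contrast)
        stats.write_tsv(cdir / "stats.tsv")

        edge_table = deg_select.score_edges(stats, net)
        edge_table.write_tsv(cdir / "edge_scores.tsv")
        threshold = deg_select.find_hes_threshold(edge_table)
        threshold.to_json(cdir / "hes.json")
        degs = deg_select.select_degs(edge_table, threshold, stats)
        degs.write_tsv(cdir / "degs.tsv")
        retained, bin_edges, counts = deg_select.high_edges_export(
            edge_table, threshold
        )
        retained.to_csv(cdir / "high_edges.tsv", sep="\t", index=False)
        (cdir / "edge_histogram.json").write_text(json.dumps({
            "bin_edges": bin_edges.tolist(), "counts": counts.tolist(),
        }) + "\n")

        rows, skipped = spia_core.run_spia(
            collection, stats, degs,
            n_boot=config.n_boot, seed=config.seed,
        )
        log["excluded_pathways"][label] = skipped
        spia_core.write_spia_tsv(rows, cdir / "spia_results.tsv")
        (cdir / "report.txt").write_text(format_results_table(rows))

        scores = {r.pathway_id: r.p_g for r in rows}
        summary = ko_roc_eval.evaluate_method_scores(
            collection, config.ko_gene, scores, n_excluded=len(skipped)
        )
        summary.to_json(cdir / "roc_summary.json")
        benchmark = ko_roc_eval.label_pathways_by_ko_gene(
            collection, config.ko_gene, scores
        )
        ko_roc_eval.roc_curve(benchmark).write_tsv(cdir / "roc_points.tsv")

        roc_summaries[label] = summary
        spia_tables[label] = rows
        deg_sets[label] = degs

    if set(config.contrasts) == {"A", "B", "C"}:
        partition = venn_core.venn_partition(
            deg_sets["A"].genes, deg_sets["B"].genes, deg_sets["C"].genes
        )
        ranked = venn_core.rank_all_regions(partition, deg_sets)
        venn_core.write_venn_tsv(ranked, out_dir / "venn.tsv")

    manifest: dict[str, str] = {}
    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name not in {"manifest.json", "run.log"}:
            manifest[str(path.relative_to(out_dir))] = _sha256(path)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (out_dir / "run.log").write_text(json.dumps(log, indent=2, default=str) + "\n")
    return RunArtifacts(
        out_dir=out_dir,
        manifest=manifest,
        log=log,
        roc_summaries=roc_summaries,
        spia_tables=spia_tables,
        deg_sets=deg_sets,
    )
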