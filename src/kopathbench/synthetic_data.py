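"""Synthetic study generator: pathway collections, KGML fixtures, expression.

Emulates the structure of a knockout microarray study with three two-group
contrasts (septic KO vs septic WT, septic KO vs untreated WT, septic WT vs
untreated WT), a knockout gene planted in a known subset of pathways, and
log-scale expression with group mean shifts propagated along signed pathway
edges downstream of the knockout gene.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from xml.etree import ElementTree
from xml.dom import minidom

import numpy as np
import pandas as pd

from .errors import ValidationError
from .pathway_model import PathwayCollection, PathwayGraph

GENOTYPES = ("WT", "KO")
TREATMENTS = ("untreated", "septic")
#: group label -> (genotype, treatment); untreated KO is not simulated.
GROUPS = {
    "untreated_WT": ("WT", "untreated"),
    "septic_WT": ("WT", "septic"),
    "septic_KO": ("KO", "septic"),
}


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one synthetic study."""

    n_genes: int = 2000
    n_pathways: int = 30
    pathway_size_range: tuple[int, int] = (8, 20)
    ko_gene: str = "G0001"
    n_positive_pathways: int = 5
    delta_treatment: float = 1.5
    delta_ko: float = 1.5
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    n_replicates: int = 3
    inhibition_fraction: float = 0.25
    mean_out_degree: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.pathway_size_range
        if self.n_positive_pathways > self.n_pathways:
            raise ValidationError(
                "n_positive_pathways must not exceed n_pathways "
                f"({self.n_positive_pathways} > {self.n_pathways})"
            )
        if lo < 3:
            raise ValidationError("pathway_size_range.min must be >= 3")
        if lo > hi:
            raise ValidationError("pathway_size_range must satisfy min <= max")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if self.n_genes < hi:
            raise ValidationError("n_genes must cover the largest pathway size")
        if not 0.0 <= self.inhibition_fraction <= 1.0:
            raise ValidationError("inhibition_fraction must lie in [0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth planted by the simulator."""

    ko_gene: str
    positive_pathway_ids: frozenset[str]
    #: per positive pathway: gene -> propagated sign (+1/-1) of the
    #: treatment shift; the knockout gene itself carries +1.
    perturbed_genes: dict[str, dict[str, int]] = field(default_factory=dict)

    def all_perturbed(self) -> dict[str, int]:
        """Gene -> sign union over pathways (first pathway wins on clash)."""
        union: dict[str, int] = {}
        for pid in sorted(self.perturbed_genes):
            for gene, sign in self.perturbed_genes[pid].items():
                union.setdefault(gene, sign)
        return union


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _downstream_signs(pathway: PathwayGraph, source: str) -> dict[str, int]:
    """Propagated sign for ``source`` and its descendants.

    The sign of a gene is the product of edge signs along the first path
    discovered from ``source`` in breadth-first order; ``source`` itself
    gets +1.
    """
    signs: dict[str, int] = {source: +1}
    adjacency: dict[str, list[tuple[str, int]]] = {}
    for src, dst, beta, _ in pathway.edges:
        adjacency.setdefault(src, []).append((dst, beta))
    frontier = [source]
    while frontier:
        nxt: list[str] = []
        for node in frontier:
            for dst, beta in sorted(adjacency.get(node, ())):
                if dst not in signs:
                    signs[dst] = signs[node] * beta
                    nxt.append(dst)
        frontier = nxt
    return signs


def _simulate_one_pathway(
    rng: np.random.Generator,
    pathway_id: str,
    genes: list[str],
    params: SimulationParams,
) -> PathwayGraph:
    """Random connected DAG over ``genes`` in the given topological order.

    Each node after the first receives one incoming edge from a random
    earlier node (connectivity), then extra forward edges are added with
    out-degree ~ Poisson(mean_out_degree).  Signs are -1 with probability
    ``inhibition_fraction``, else +1.
    """
    n = len(genes)
    pairs: set[tuple[int, int]] = set()
    for j in range(1, n):
        i = int(rng.integers(0, j))
        pairs.add((i, j))
    for i in range(n - 1):
        extra = int(rng.poisson(params.mean_out_degree))
        if extra <= 0:
            continue
        candidates = np.arange(i + 1, n)
        chosen = rng.choice(candidates, size=min(extra, len(candidates)), replace=False)
        for j in chosen:
            pairs.add((i, int(j)))
    edges = []
    for i, j in sorted(pairs):
        beta = -1 if rng.random() < params.inhibition_fraction else +1
        subtype = "activation" if beta > 0 else "inhibition"
        edges.append((genes[i], genes[j], beta, subtype))
    return PathwayGraph(
        pathway_id=pathway_id,
        name=f"synthetic pathway {pathway_id}",
        nodes=frozenset(genes),
        edges=tuple(edges),
    )


def simulate_pathway_collection(
    params: SimulationParams,
) -> tuple[PathwayCollection, PlantedTruth]:
    """Generate ``n_pathways`` signed DAGs over a shared gene universe.

    Exactly ``n_positive_pathways`` contain ``ko_gene`` (placed at a random
    topological position so it has downstream targets); no negative pathway
    contains it.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    universe = _gene_names(params.n_genes)
    if params.ko_gene not in universe:
        universe = [params.ko_gene] + universe[:-1]
    others = [g for g in universe if g != params.ko_gene]
    lo, hi = params.pathway_size_range

    pathways: list[PathwayGraph] = []
    perturbed: dict[str, dict[str, int]] = {}
    positive_ids: list[str] = []
    width = max(5, len(str(params.n_pathways)))
    for k in range(params.n_pathways):
        pathway_id = f"syn{k + 1:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        is_positive = k < params.n_positive_pathways
        if is_positive:
            members = list(rng.choice(others, size=size - 1, replace=False))
            # upstream placement (adaptor-like role) guarantees the knockout
            # gene has downstream targets to perturb
            pos = int(rng.integers(0, max(1, size // 2)))
            members.insert(pos, params.ko_gene)
        else:
            members = list(rng.choice(others, size=size, replace=False))
        graph = _simulate_one_pathway(rng, pathway_id, members, params)
        pathways.append(graph)
        if is_positive:
            positive_ids.append(pathway_id)
            perturbed[pathway_id] = _downstream_signs(graph, params.ko_gene)

    collection = PathwayCollection(
        pathways=tuple(pathways), gene_universe=frozenset(universe)
    )
    truth = PlantedTruth(
        ko_gene=params.ko_gene,
        positive_pathway_ids=frozenset(positive_ids),
        perturbed_genes=perturbed,
    )
    return collection, truth


def simulate_expression(
    params: SimulationParams,
    collection: PathwayCollection,
    truth: PlantedTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log2 expression matrix and sample metadata for the three groups.

    Baseline per-gene means are Normal(baseline_mean, baseline_sd^2) with
    i.i.d. Normal(0, noise_sd^2) noise.  Septic samples shift each planted
    perturbed gene by ``sign * delta_treatment``; septic-KO samples shift
    the knockout gene by ``-delta_ko`` on top.
    """
    params.validate()
    if truth.ko_gene != params.ko_gene:
        raise ValidationError("truth.ko_gene does not match params.ko_gene")
    missing = truth.positive_pathway_ids - set(collection.pathway_ids)
    if missing:
        raise ValidationError(
            f"truth references pathways absent from the collection: {sorted(missing)}"
        )
    rng = np.random.default_rng(params.seed + 1)
    genes = sorted(collection.gene_universe)
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    sample_ids: list[str] = []
    meta_rows: list[dict[str, str]] = []
    for group, (genotype, treatment) in GROUPS.items():
        for r in range(params.n_replicates):
            sid = f"{group}_{r + 1}"
            sample_ids.append(sid)
            meta_rows.append(
                {"sample": sid, "genotype": genotype, "treatment": treatment}
            )
    metadata = pd.DataFrame(meta_rows)

    baseline = rng.normal(params.baseline_mean, params.baseline_sd, size=n_genes)
    values = np.empty((n_genes, len(sample_ids)))
    perturbed_union = truth.all_perturbed()
    for col, row in enumerate(meta_rows):
        mean = baseline.copy()
        if row["treatment"] == "septic":
            for gene, sign in perturbed_union.items():
                mean[gene_index[gene]] += sign * params.delta_treatment
        if row["genotype"] == "KO":
            mean[gene_index[params.ko_gene]] -= params.delta_ko
        values[:, col] = mean + rng.normal(0.0, params.noise_sd, size=n_genes)

    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                          columns=sample_ids)
    return matrix, metadata


def write_kgml_fixtures(
    collection: PathwayCollection, directory: str | Path, prefix: str = "syn"
) -> list[Path]:
    """Write one well-formed KGML file per pathway; returns the paths.

    Each gene becomes a single-gene ``entry`` (name ``<prefix>:<gene>``);
    each signed edge becomes a ``relation`` with an ``activation`` or
    ``inhibition`` subtype, so files round-trip through
    :func:`kopathbench.pathway_model.parse_kgml` to graphs with identical
    signed edge sets.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for pathway in collection:
        root = ElementTree.Element(
            "pathway",
            {
                "name": f"path:{pathway.pathway_id}",
                "org": prefix,
                "number": pathway.pathway_id,
                "title": pathway.name,
            },
        )
        entry_id = {g: str(i + 1) for i, g in enumerate(pathway.sorted_nodes())}
        for gene, eid in entry_id.items():
            ElementTree.SubElement(
                root, "entry",
                {"id": eid, "name": f"{prefix}:{gene}", "type": "gene"},
            )
        for src, dst, beta, subtype in pathway.edges:
            rel = ElementTree.SubElement(
                root, "relation",
                {"entry1": entry_id[src], "entry2": entry_id[dst], "type": "PPrel"},
            )
            ElementTree.SubElement(
                rel, "subtype",
                {"name": subtype, "value": "-->" if beta > 0 else "--|"},
            )
        raw = ElementTree.tostring(root, encoding="unicode")
        pretty = minidom.parseString(raw).toprettyxml(indent="  ")
        out = directory / f"{pathway.pathway_id}.xml"
        out.write_text(pretty)
        paths.append(out)
    return paths


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    # %.17g keeps float64 round-trip exact so re-running a stage from the
    # persisted TSV reproduces downstream outputs bit-for-bit
    matrix.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def write_truth_json(
    truth: PlantedTruth, params: SimulationParams, path: str | Path
) -> None:
    payload = {
        "ko_gene": truth.ko_gene,
        "positive_pathway_ids": sorted(truth.positive_pathway_ids),
        "perturbed_genes": {
            pid: dict(sorted(gene_signs.items()))
            for pid, gene_signs in sorted(truth.perturbed_genes.items())
        },
        "seed": params.seed,
        "params": asdict(params),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
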