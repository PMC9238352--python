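import numpy as np
import pytest

from kopathbench.deg_select import DegSet
from kopathbench.pathway_model import PathwayCollection, PathwayGraph
from kopathbench.synthetic_data import (
    SimulationParams,
    simulate_expression,
    simulate_pathway_collection,
)

import pandas as pd


def make_pathway(pathway_id, edges, extra_nodes=()):
    """Build a PathwayGraph from (src, dst, beta) triples."""
    nodes = set(extra_nodes)
    full_edges = []
    for src, dst, beta in edges:
        nodes.update((src, dst))
        subtype = "activation" if beta > 0 else "inhibition"
        full_edges.append((src, dst, beta, subtype))
    return PathwayGraph(
        pathway_id=pathway_id,
        name=f"pathway {pathway_id}",
        nodes=frozenset(nodes),
        edges=tuple(full_edges),
    )


def make_deg_set(label, gene_lfc, best_es=None):
    genes = sorted(gene_lfc)
    table = pd.DataFrame(
        {
            "lfc": [gene_lfc[g] for g in genes],
            "best_ES": [(best_es or {}).get(g, 1.0) for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return DegSet(label=label, table=table)


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams(seed=7)


@pytest.fixture(scope="session")
def small_study(default_params):
    """Collection + truth + expression for the default synthetic study."""
    collection, truth = simulate_pathway_collection(default_params)
    values, metadata = simulate_expression(default_params, collection, truth)
    return default_params, collection, truth, values, metadata


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dag_pathway(rng, pathway_id="dag", max_nodes=8):
    """Random signed DAG with 2..max_nodes nodes (for oracle comparisons)."""
    n = int(rng.integers(2, max_nodes + 1))
    genes = [f"N{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                beta = -1 if rng.random() < 0.3 else +1
                edges.append((genes[i], genes[j], beta))
    return make_pathway(pathway_id, edges, extra_nodes=genes)


def pf_path_enumeration(pathway, delta_e_map):
    """Brute-force oracle: PF(i) = dE(i) + sum over all directed paths
    ending at i of dE(start) * prod(beta / Nds) along the path.

    Valid on DAGs only (path enumeration terminates).
    """
    nds = pathway.nds
    weights = {}
    for src, dst, beta, _ in pathway.edges:
        weights[(src, dst)] = weights.get((src, dst), 0.0) + beta / nds[src]
    children = {}
    for src, dst in weights:
        children.setdefault(src, []).append(dst)

    pf = {g: delta_e_map.get(g, 0.0) for g in pathway.nodes}

    def walk(node, contribution):
        for child in children.get(node, ()):
            c = contribution * weights[(node, child)]
            pf[child] += c
            walk(child, c)

    for g in pathway.nodes:
        start = delta_e_map.get(g, 0.0)
        if start != 0.0:
            walk(g, start)
    return pf
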