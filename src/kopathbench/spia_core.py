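"""Topology-based pathway perturbation scoring.

Per pathway: the DEG fold-changes enter as the signed input vector dE; the
net perturbation factor PF solves PF = dE + B @ PF on the normalized signed
influence matrix B; the accumulated perturbation Acc = PF - dE sums to the
pathway statistic tA.  Significance combines a hypergeometric
over-representation p-value (pNDE) with a bootstrap p-value of tA (pPERT)
into pG = c - c*ln(c), BH-adjusted across pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .deg_select import DegSet
from .errors import NotComputableError, ValidationError
from .expression_stats import ContrastResult
from .pathway_model import PathwayCollection, PathwayGraph, build_beta_matrix

logger = logging.getLogger(__name__)

DEFAULT_N_BOOT = 2000
_DET_TOL = 1e-12


@dataclass
class PerturbationState:
    """Per-gene perturbation vectors for one pathway."""

    node_order: list[str]
    delta_e: np.ndarray  # signed log2 inputs (lfc for DEGs, else 0)
    pf: np.ndarray | None = None  # net perturbation factors
    acc: np.ndarray | None = None  # PF - dE

    @property
    def nde(self) -> int:
        return int(np.count_nonzero(self.delta_e))

    @property
    def ta(self) -> float:
        if self.acc is None:
            raise ValidationError("net perturbation has not been computed")
        return float(self.acc.sum())


@dataclass
class SpiaResult:
    """One pathway's scoring record (one output-table row)."""

    pathway_id: str
    name: str
    psize: int
    nde: int
    ta: float
    p_nde: float
    p_pert: float
    p_g: float
    p_g_fdr: float
    status: str  # "Activated", "Inhibited" or "NA"


def delta_e(degs: DegSet, pathway: PathwayGraph) -> PerturbationState:
    """Signed input vector: dE(g) = lfc(g) for DEGs on the pathway, else 0."""
    order = pathway.sorted_nodes()
    values = np.zeros(len(order))
    deg_lfc = degs.lfc
    for i, gene in enumerate(order):
        if gene in degs.genes:
            values[i] = float(deg_lfc[gene])
    return PerturbationState(node_order=order, delta_e=values)


def net_perturbation(B: np.ndarray, state: PerturbationState) -> PerturbationState:
    """Solve PF = dE + B @ PF; fill in PF, Acc and (via ``ta``) the statistic.

    Raises :class:`NotComputableError` when (I - B) is singular; the caller
    flags the pathway and excludes it from downstream scoring.
    """
    n = len(state.delta_e)
    if B.shape != (n, n):
        raise ValidationError("B matrix does not match the dE vector length")
    system = np.eye(n) - B
    if abs(np.linalg.det(system)) <= _DET_TOL:
        raise NotComputableError("(I - B) is singular; pathway not computable")
    state.pf = np.linalg.solve(system, state.delta_e)
    state.acc = state.pf - state.delta_e
    return state


def _net_influence_coefficients(B: np.ndarray) -> np.ndarray:
    """Column vector c with tA(dE) = c @ dE, i.e. colsums of (I-B)^-1 - I."""
    n = B.shape[0]
    system = np.eye(n) - B
    if abs(np.linalg.det(system)) <= _DET_TOL:
        raise NotComputableError("(I - B) is singular; pathway not computable")
    M = np.linalg.inv(system)
    return (M - np.eye(n)).sum(axis=0)


def p_nde(nde: int, psize_measured: int, n_deg_total: int, n_universe: int) -> float:
    """Upper-tail hypergeometric P(X >= NDE).

    Population ``n_universe``, successes ``psize_measured`` (measured
    pathway genes), draws ``n_deg_total`` (all DEGs).  NDE = 0 gives 1.
    """
    if not (0 <= nde <= min(psize_measured, n_deg_total)):
        raise ValidationError(
            f"inconsistent counts: NDE={nde}, pathway={psize_measured}, "
            f"DEGs={n_deg_total}"
        )
    if max(psize_measured, n_deg_total) > n_universe:
        raise ValidationError("pathway/DEG counts exceed the gene universe")
    if nde == 0:
        return 1.0
    value = float(
        sps.hypergeom.sf(nde - 1, n_universe, psize_measured, n_deg_total)
    )
    return min(max(value, 0.0), 1.0)


def p_pert(
    pathway: PathwayGraph,
    degs: DegSet,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, str, float]:
    """Bootstrap p-value of tA and the Activated/Inhibited status.

    Each of ``n_boot`` resamples assigns NDE fold-changes drawn with
    replacement from the full DEG pool to NDE uniformly chosen pathway
    genes and recomputes tA; the p-value is the add-one two-sided tail
    around the null median.  NDE = 0 returns (1.0, "NA", 0.0).
    """
    if n_boot < 200:
        raise ValidationError("n_boot must be >= 200")
    state = delta_e(degs, pathway)
    if state.nde == 0:
        return 1.0, "NA", 0.0
    B, order = build_beta_matrix(pathway, node_order=state.node_order)
    coef = _net_influence_coefficients(B)
    ta_obs = float(coef @ state.delta_e)

    rng = np.random.default_rng(seed)
    pool = degs.lfc.to_numpy()
    n = len(order)
    nde = state.nde
    # positions: n_boot draws of NDE distinct gene slots; lfcs with replacement
    positions = np.argsort(rng.random((n_boot, n)), axis=1)[:, :nde]
    lfcs = pool[rng.integers(0, len(pool), size=(n_boot, nde))]
    ta_null = (coef[positions] * lfcs).sum(axis=1)

    med = float(np.median(ta_null))
    # tolerance absorbs summation-order rounding so exact ties count as extreme
    tol = 1e-9 * max(1.0, abs(ta_obs), float(np.max(np.abs(ta_null))))
    extreme = int(np.sum(np.abs(ta_null - med) >= abs(ta_obs - med) - tol))
    p_value = (1 + extreme) / (n_boot + 1)
    status = "Activated" if ta_obs > med else "Inhibited"
    return float(p_value), status, med


def combine_pg(p_nde_value: float, p_pert_value: float) -> float:
    """Fisher-product combination pG = c - c*ln(c), c = pNDE * pPERT."""
    for name, v in (("pNDE", p_nde_value), ("pPERT", p_pert_value)):
        if not 0.0 < v <= 1.0:
            raise ValidationError(f"{name} must lie in (0, 1], got {v}")
    c = p_nde_value * p_pert_value
    return float(c - c * np.log(c))


def fdr_bh(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def run_spia(
    collection: PathwayCollection,
    stats: ContrastResult,
    degs: DegSet,
    universe: frozenset[str] | None = None,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> tuple[list[SpiaResult], list[str]]:
    """Score every pathway; returns (rows sorted by pGFdr, skipped ids).

    The over-representation universe defaults to measured genes that map to
    at least one pathway in the collection.  Pathways with a singular
    (I - B) system are flagged and excluded.
    """
    measured = frozenset(stats.table.index)
    if universe is None:
        universe = collection.pathway_gene_union() & measured
    universe = frozenset(universe)
    deg_genes = degs.genes & universe
    n_deg_total = len(deg_genes)
    n_universe = len(universe)

    root_seq = np.random.SeedSequence(seed)
    child_seeds = root_seq.spawn(len(collection))

    rows: list[SpiaResult] = []
    skipped: list[str] = []
    for i, pathway in enumerate(collection):
        measured_nodes = pathway.nodes & universe
        nde_genes = deg_genes & pathway.nodes
        nde = len(nde_genes)
        try:
            state = delta_e(degs, pathway)
            B, _ = build_beta_matrix(pathway, node_order=state.node_order)
            state = net_perturbation(B, state)
            pert, status, _ = p_pert(
                pathway, degs, n_boot=n_boot, seed=child_seeds[i]
            ) if nde > 0 else (1.0, "NA", 0.0)
        except NotComputableError:
            logger.warning("pathway %s not computable; skipped", pathway.pathway_id)
            skipped.append(pathway.pathway_id)
            continue
        nde_p = p_nde(nde, len(measured_nodes), n_deg_total, n_universe)
        pg = combine_pg(nde_p, pert)
        rows.append(SpiaResult(
            pathway_id=pathway.pathway_id,
            name=pathway.name,
            psize=pathway.psize,
            nde=nde,
            ta=state.ta,
            p_nde=nde_p,
            p_pert=pert,
            p_g=pg,
            p_g_fdr=np.nan,
            status=status,
        ))
    if rows:
        adjusted = fdr_bh([r.p_g for r in rows])
        for row, adj in zip(rows, adjusted):
            row.p_g_fdr = float(adj)
        rows.sort(key=lambda r: (r.p_g_fdr, r.p_g, r.pathway_id))
    return rows, skipped


def results_to_frame(rows: list[SpiaResult]) -> pd.DataFrame:
    """Tabular form with the printed columns plus internals."""
    return pd.DataFrame(
        {
            "ID": [r.pathway_id for r in rows],
            "Name": [r.name for r in rows],
            "Status": [r.status for r in rows],
            "pSize": [r.psize for r in rows],
            "NDE": [r.nde for r in rows],
            "DEG_pct": [100.0 * r.nde / r.psize if r.psize else 0.0 for r in rows],
            "tA": [r.ta for r in rows],
            "pNDE": [r.p_nde for r in rows],
            "pPERT": [r.p_pert for r in rows],
            "pG": [r.p_g for r in rows],
            "pGFdr": [r.p_g_fdr for r in rows],
        }
    )


def write_spia_tsv(rows: list[SpiaResult], path: str | Path) -> None:
    results_to_frame(rows).to_csv(path, sep="\t", index=False)
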