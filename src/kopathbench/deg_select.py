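"""Edge scoring and change-point DEG selection.

Each measured global-network edge gets a nonnegative score combining the
fold-change and p-value evidence of its two endpoint genes; a single
change point on the descending-sorted score sequence defines the
high-edge-score cutoff, and genes incident to a retained edge form the
DEG set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NoThresholdError, ValidationError
from .expression_stats import ContrastResult
from .pathway_model import GlobalNetwork

logger = logging.getLogger(__name__)

MIN_EDGES_FOR_THRESHOLD = 20
#: variance floor inside segment likelihoods (constant-segment guard)
_SEG_VAR_FLOOR = 1e-12


@dataclass
class EdgeScoreTable:
    """Per-edge scores with the endpoint gene weights that produced them."""

    label: str
    table: pd.DataFrame  # columns: src, dst, w_src, w_dst, ES
    n_skipped_unmeasured: int = 0

    @property
    def scores(self) -> np.ndarray:
        return self.table["ES"].to_numpy()

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class HesThreshold:
    """High-edge-score cutoff located by change-point detection."""

    hes1_value: float
    changepoint_index: int  # rank position in descending-sorted scores
    n_edges_retained: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "hes1_value": self.hes1_value,
            "changepoint_index": self.changepoint_index,
            "n_edges_retained": self.n_edges_retained,
        }, indent=2) + "\n")


@dataclass
class DegSet:
    """Genes incident to at least one retained edge, with their evidence."""

    label: str
    table: pd.DataFrame  # index gene, columns lfc, best_ES

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.table.index)

    @property
    def lfc(self) -> pd.Series:
        return self.table["lfc"]

    @property
    def best_edge_score(self) -> pd.Series:
        return self.table["best_ES"]

    def __len__(self) -> int:
        return len(self.table)

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


def gene_weight(lfc: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Evidence weight per gene: |lfc| * (-log10 p)."""
    return np.abs(lfc) * (-np.log10(p))


def score_edges(stats: ContrastResult, net: GlobalNetwork) -> EdgeScoreTable:
    """Score every global-network edge with both endpoints measured.

    ES(u, v) = sqrt(w_u * w_v) with w_g = |lfc_g| * (-log10 p_g); edges with
    an unmeasured endpoint are skipped and counted.
    """
    measured = set(stats.table.index)
    w = pd.Series(
        gene_weight(stats.lfc.to_numpy(), stats.p.to_numpy()),
        index=stats.table.index,
    )
    rows = []
    skipped = 0
    for src, dst in sorted(net.edges):
        if src not in measured or dst not in measured:
            skipped += 1
            continue
        w_src, w_dst = float(w[src]), float(w[dst])
        rows.append((src, dst, w_src, w_dst, float(np.sqrt(w_src * w_dst))))
    if not rows:
        raise ValidationError(
            "no network edge has both endpoints in the measured gene set"
        )
    if skipped:
        logger.info(
            "contrast %s: skipped %d edges with unmeasured endpoints",
            stats.label, skipped,
        )
    table = pd.DataFrame(rows, columns=["src", "dst", "w_src", "w_dst", "ES"])
    return EdgeScoreTable(label=stats.label, table=table,
                          n_skipped_unmeasured=skipped)


def _segment_cost(prefix: np.ndarray, prefix_sq: np.ndarray,
                  start: int, stop: int) -> float:
    """Gaussian negative log-likelihood cost (up to constants) of x[start:stop]."""
    m = stop - start
    s = prefix[stop] - prefix[start]
    ss = prefix_sq[stop] - prefix_sq[start]
    var = max(ss / m - (s / m) ** 2, _SEG_VAR_FLOOR)
    return m * np.log(var)


def amoc_changepoint(scores_desc: np.ndarray, min_segment: int = 2) -> int:
    """At-most-one-change split of a sequence under a Gaussian mean+variance model.

    Scans every admissible split of ``scores_desc`` into two segments,
    scoring each by the two-segment Gaussian log-likelihood penalized by the
    modified-BIC term ``log(k (n - k) / n)`` on the split position.  Returns
    the index ``k`` such that the first segment is ``scores_desc[:k]``.
    """
    x = np.asarray(scores_desc, dtype=float)
    n = len(x)
    if n < 2 * min_segment:
        raise NoThresholdError(f"need at least {2 * min_segment} scores, got {n}")
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix_sq = np.concatenate([[0.0], np.cumsum(x * x)])
    best_k, best_obj = -1, np.inf
    for k in range(min_segment, n - min_segment + 1):
        cost = (
            _segment_cost(prefix, prefix_sq, 0, k)
            + _segment_cost(prefix, prefix_sq, k, n)
            + np.log(k * (n - k) / n)
        )
        if cost < best_obj:
            best_obj, best_k = cost, k
    return best_k


def find_hes_threshold(table: EdgeScoreTable) -> HesThreshold:
    """Locate the high-edge-score cutoff on the sorted score distribution.

    Scores are sorted descending; the single change point of the sorted
    sequence defines the cutoff as the score at the change-point index
    (the last edge of the high segment).  Ties at the cutoff are retained.
    """
    scores = np.sort(table.scores)[::-1]
    if len(scores) < MIN_EDGES_FOR_THRESHOLD:
        raise NoThresholdError(
            f"need >= {MIN_EDGES_FOR_THRESHOLD} scored edges, got {len(scores)}"
        )
    if np.ptp(scores) == 0:
        raise NoThresholdError("all edge scores are equal; no change point")
    k = amoc_changepoint(scores)
    hes1 = float(scores[k - 1])
    n_retained = int(np.sum(table.scores >= hes1))
    return HesThreshold(hes1_value=hes1, changepoint_index=k,
                        n_edges_retained=n_retained)


def select_degs(
    table: EdgeScoreTable,
    threshold: HesThreshold | float,
    stats: ContrastResult,
) -> DegSet:
    """Genes incident to at least one edge scoring at or above the cutoff."""
    cutoff = (
        threshold.hes1_value
        if isinstance(threshold, HesThreshold)
        else float(threshold)
    )
    retained = table.table[table.table["ES"] >= cutoff]
    best: dict[str, float] = {}
    for row in retained.itertuples(index=False):
        for gene in (row.src, row.dst):
            if gene not in best or row.ES > best[gene]:
                best[gene] = float(row.ES)
    genes = sorted(best)
    deg_table = pd.DataFrame(
        {
            "lfc": [float(stats.lfc[g]) for g in genes],
            "best_ES": [best[g] for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return DegSet(label=table.label, table=deg_table)


def high_edges_export(
    table: EdgeScoreTable,
    threshold: HesThreshold | float,
    n_bins: int = 50,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Retained-edge table plus a histogram of all edge scores.

    Returns ``(retained_edges, bin_edges, counts)``; the histogram covers
    every scored edge so counts always sum to the table size.
    """
    cutoff = (
        threshold.hes1_value
        if isinstance(threshold, HesThreshold)
        else float(threshold)
    )
    retained = table.table[table.table["ES"] >= cutoff].reset_index(drop=True)
    counts, bin_edges = np.histogram(table.scores, bins=n_bins)
    return retained, bin_edges, counts
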