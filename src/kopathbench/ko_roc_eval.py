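"""Knockout ground-truth ROC benchmarking of per-pathway p-values.

Pathways containing the knockout gene are the positives; a method's
per-pathway p-values are the scores, oriented so that smaller means a
stronger positive call.  The metric panel covers AUC with a DeLong 95% CI,
partial AUCs over the high-specificity and high-sensitivity regions in
original and McClish-corrected formats, and the Youden-optimal threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats as sps

from .errors import BenchmarkError, ValidationError
from .pathway_model import PathwayCollection

logger = logging.getLogger(__name__)

DEFAULT_PAUC_BOUNDS = (0.9, 1.0)


@dataclass
class KoBenchmark:
    """Labeled score table: True marks pathways containing the KO gene."""

    ko_gene: str
    pathway_ids: list[str]
    labels: np.ndarray  # bool, True = positive
    scores: np.ndarray  # p-values; lower = stronger call

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.pathway_ids) != len(self.labels) or len(self.labels) != len(self.scores):
            raise ValidationError("pathway_ids, labels and scores must align")
        if not self.labels.any() or self.labels.all():
            raise BenchmarkError(
                "ROC undefined: need at least one positive and one negative pathway"
            )

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int((~self.labels).sum())


@dataclass
class RocCurve:
    """Operating points as (threshold, sensitivity, specificity) triples."""

    points: list[tuple[float, float, float]]

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        arr = np.asarray(self.points, dtype=float)
        return arr[:, 0], arr[:, 1], arr[:, 2]

    def write_tsv(self, path: str | Path) -> None:
        lines = ["threshold\tsensitivity\tspecificity"]
        for t, se, sp in self.points:
            lines.append(f"{t:.10g}\t{se:.10g}\t{sp:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RocSummary:
    """The full metric panel for one method on one contrast."""

    auc: float
    ci_low: float
    ci_high: float
    pauc_sp: float
    pauc_se: float
    pauc_sp_corrected: float
    pauc_se_corrected: float
    youden_threshold: float
    youden_sens: float
    youden_spec: float
    n_positive: int
    n_negative: int
    n_excluded: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def label_pathways_by_ko_gene(
    collection: PathwayCollection,
    ko_gene: str,
    scores: Mapping[str, float],
) -> KoBenchmark:
    """Label each scored pathway positive iff it contains the knockout gene."""
    if not ko_gene:
        raise ValidationError("ko_gene must be nonempty")
    mismatched = sorted(set(scores) - set(collection.pathway_ids))
    if mismatched:
        raise ValidationError(
            f"scores reference pathways absent from the collection: {mismatched}"
        )
    ids, labels, values = [], [], []
    for pathway in collection:
        if pathway.pathway_id not in scores:
            continue
        ids.append(pathway.pathway_id)
        labels.append(ko_gene in pathway.nodes)
        values.append(float(scores[pathway.pathway_id]))
    return KoBenchmark(
        ko_gene=ko_gene,
        pathway_ids=ids,
        labels=np.array(labels, dtype=bool),
        scores=np.array(values, dtype=float),
    )


def _sens_spec_at(benchmark: KoBenchmark, threshold: float) -> tuple[float, float]:
    called = benchmark.scores <= threshold
    tp = int(np.sum(called & benchmark.labels))
    fp = int(np.sum(called & ~benchmark.labels))
    return tp / benchmark.n_positive, 1.0 - fp / benchmark.n_negative


def roc_curve(benchmark: KoBenchmark) -> RocCurve:
    """Operating points over all unique scores.

    A pathway is called positive when its p-value is at or below the
    threshold.  Thresholds are reported as midpoints between adjacent
    distinct scores (the top score itself for the call-everything point);
    the call-nothing endpoint carries threshold 0.
    """
    unique = np.unique(benchmark.scores)
    points: list[tuple[float, float, float]] = [(0.0, 0.0, 1.0)]
    for i, u in enumerate(unique):
        threshold = (
            (u + unique[i + 1]) / 2.0 if i + 1 < len(unique) else float(u)
        )
        sens, spec = _sens_spec_at(benchmark, u)
        points.append((float(threshold), sens, spec))
    return RocCurve(points=points)


def auc(benchmark: KoBenchmark) -> float:
    """Mann-Whitney AUC with ties counting one half.

    Scores are p-values, so a positive pathway is concordant when its score
    is *smaller* than a negative pathway's.
    """
    pos = benchmark.scores[benchmark.labels]
    neg = benchmark.scores[~benchmark.labels]
    less = (pos[:, None] < neg[None, :]).sum()
    tied = (pos[:, None] == neg[None, :]).sum()
    return float((less + 0.5 * tied) / (len(pos) * len(neg)))


def delong_ci(
    benchmark: KoBenchmark, level: float = 0.95
) -> tuple[float, float, float]:
    """(auc, ci_low, ci_high) via DeLong's placement-value variance.

    Perfect separation yields zero variance and a degenerate CI at the AUC
    (logged).
    """
    # orient so larger = more positive, matching the classic derivation
    pos = -benchmark.scores[benchmark.labels]
    neg = -benchmark.scores[~benchmark.labels]
    m, n = len(pos), len(neg)
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    auc_value = float(psi.mean())
    v10 = psi.mean(axis=1)  # placements of positives
    v01 = psi.mean(axis=0)  # placements of negatives
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    variance = s10 / m + s01 / n
    if variance <= 0:
        logger.info("DeLong variance is zero (perfect separation); degenerate CI")
        return auc_value, auc_value, auc_value
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    half = z * float(np.sqrt(variance))
    return auc_value, max(auc_value - half, 0.0), min(auc_value + half, 1.0)


def _clip_polyline(
    x: np.ndarray, y: np.ndarray, lo: float, hi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Clip a piecewise-linear curve (x nondecreasing) to x in [lo, hi]."""
    xs, ys = [], []
    for i in range(len(x) - 1):
        x0, x1, y0, y1 = x[i], x[i + 1], y[i], y[i + 1]
        if x1 < lo or x0 > hi:
            continue
        if x1 == x0:
            if lo <= x0 <= hi:
                xs.extend([x0, x1])
                ys.extend([y0, y1])
            continue
        xa, xb = max(x0, lo), min(x1, hi)
        slope = (y1 - y0) / (x1 - x0)
        xs.extend([xa, xb])
        ys.extend([y0 + slope * (xa - x0), y0 + slope * (xb - x0)])
    if not xs:
        raise ValidationError("partial-AUC region does not intersect the curve")
    return np.asarray(xs), np.asarray(ys)


def partial_auc(
    benchmark: KoBenchmark,
    region: str = "specificity",
    bounds: tuple[float, float] = DEFAULT_PAUC_BOUNDS,
    corrected: bool = False,
) -> float:
    """Partial area over a specificity or sensitivity band.

    For the specificity region the area is ``integral of sensitivity over
    (1 - specificity)`` restricted to the band; for the sensitivity region
    it is ``integral of specificity over sensitivity``, so the full-region
    value equals the AUC either way.  The corrected format applies the
    McClish standardization ``(1 + (pA - pA_min) / (pA_max - pA_min)) / 2``
    with ``pA_max`` the band width and ``pA_min = width^2 / 2``, clipped to
    [0.5, 1] (curves below the chance line are reported at the floor).
    """
    lo, hi = bounds
    if not (0.0 <= lo < hi <= 1.0):
        raise ValidationError(f"invalid partial-AUC bounds {bounds}")
    curve = roc_curve(benchmark)
    _, sens, spec = curve.as_arrays()
    if region == "specificity":
        x, y = 1.0 - spec, sens  # x nondecreasing along the curve
        xa, xb = 1.0 - hi, 1.0 - lo
    elif region == "sensitivity":
        x, y = sens, spec
        xa, xb = lo, hi
    else:
        raise ValidationError(f"unknown region {region!r}")
    cx, cy = _clip_polyline(x, y, xa, xb)
    value = float(np.trapezoid(cy, cx))
    if not corrected:
        return value
    width = hi - lo
    pa_max = width
    pa_min = width * width / 2.0
    standardized = (1.0 + (value - pa_min) / (pa_max - pa_min)) / 2.0
    return float(np.clip(standardized, 0.5, 1.0))


def youden_best(benchmark: KoBenchmark) -> tuple[float, float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    The threshold is the midpoint between the adjacent distinct scores
    straddling the optimum.  Ties on J prefer higher specificity, then the
    lower threshold.
    """
    curve = roc_curve(benchmark)
    best = None
    for threshold, sens, spec in curve.points[1:]:  # skip the call-nothing point
        j = sens + spec - 1.0
        key = (-j, -spec, threshold)
        if best is None or key < best[0]:
            best = (key, threshold, sens, spec)
    assert best is not None
    return best[1], best[2], best[3]


def summarize(benchmark: KoBenchmark, n_excluded: int = 0) -> RocSummary:
    """Compute the full metric panel for one benchmark."""
    auc_value, ci_low, ci_high = delong_ci(benchmark)
    threshold, sens, spec = youden_best(benchmark)
    return RocSummary(
        auc=auc_value,
        ci_low=ci_low,
        ci_high=ci_high,
        pauc_sp=partial_auc(benchmark, "specificity"),
        pauc_se=partial_auc(benchmark, "sensitivity"),
        pauc_sp_corrected=partial_auc(benchmark, "specificity", corrected=True),
        pauc_se_corrected=partial_auc(benchmark, "sensitivity", corrected=True),
        youden_threshold=threshold,
        youden_sens=sens,
        youden_spec=spec,
        n_positive=benchmark.n_positive,
        n_negative=benchmark.n_negative,
        n_excluded=n_excluded,
    )


def evaluate_method_scores(
    collection: PathwayCollection,
    ko_gene: str,
    scores: Mapping[str, float],
    n_excluded: int = 0,
) -> RocSummary:
    """Benchmark any method's per-pathway p-value table against KO truth."""
    benchmark = label_pathways_by_ko_gene(collection, ko_gene, scores)
    return summarize(benchmark, n_excluded=n_excluded)
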