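"""Expression I/O and per-gene two-group statistics.

The matrix contract starts at normalized log2 intensities; each contrast is
a Welch unequal-variance t-test with log2 fold-change = mean(case) -
mean(reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

#: floor on the squared standard error, guards constant groups
VARIANCE_FLOOR = 1e-8
#: floor on p-values so -log10(p) stays finite
P_FLOOR = 1e-300

#: contrast label -> ((case genotype, case treatment), (ref genotype, ref treatment))
DEFAULT_CONTRASTS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "A": (("KO", "septic"), ("WT", "septic")),
    "B": (("KO", "septic"), ("WT", "untreated")),
    "C": (("WT", "septic"), ("WT", "untreated")),
}


@dataclass(frozen=True)
class ContrastSpec:
    """One two-group comparison: (genotype, treatment) case vs reference."""

    label: str
    case: tuple[str, str]
    reference: tuple[str, str]

    def __post_init__(self) -> None:
        if self.case == self.reference:
            raise ValidationError("case and reference groups must differ")

    @classmethod
    def default(cls, label: str) -> "ContrastSpec":
        if label not in DEFAULT_CONTRASTS:
            raise ValidationError(f"unknown default contrast label {label!r}")
        case, ref = DEFAULT_CONTRASTS[label]
        return cls(label=label, case=case, reference=ref)


@dataclass
class ExpressionMatrix:
    """Log2 expression values with attached sample annotations."""

    values: pd.DataFrame  # genes x samples
    metadata: pd.DataFrame  # columns: sample, genotype, treatment

    def __post_init__(self) -> None:
        meta = self.metadata.set_index("sample")
        missing = [s for s in self.values.columns if s not in meta.index]
        if missing:
            raise ValidationError(f"metadata missing samples: {missing}")
        unknown = [s for s in meta.index if s not in self.values.columns]
        if unknown:
            raise ValidationError(f"metadata lists unknown samples: {unknown}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("expression values must be finite")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def has_duplicate_genes(self) -> bool:
        return bool(self.values.index.duplicated().any())

    def group_samples(self, genotype: str, treatment: str) -> list[str]:
        meta = self.metadata
        mask = (meta["genotype"] == genotype) & (meta["treatment"] == treatment)
        return list(meta.loc[mask, "sample"])


@dataclass
class ContrastResult:
    """Per-gene log2 fold-change and two-sided p-value for one contrast."""

    label: str
    table: pd.DataFrame  # index gene, columns lfc, p

    @property
    def lfc(self) -> pd.Series:
        return self.table["lfc"]

    @property
    def p(self) -> pd.Series:
        return self.table["p"]

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


def read_expression(
    expression_path: str | Path, metadata_path: str | Path
) -> ExpressionMatrix:
    """Read the expression TSV (first column ``gene``) and metadata TSV.

    Row order is preserved.  Duplicate gene rows are rejected here; collapse
    must be requested explicitly through :func:`collapse_probes`.
    """
    # round_trip parsing keeps persisted float64 values bit-exact
    values = pd.read_csv(
        expression_path, sep="\t", index_col=0, float_precision="round_trip"
    )
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric expression cell: {exc}") from exc
    metadata = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample", "genotype", "treatment"}
    if not required.issubset(metadata.columns):
        raise ValidationError(
            f"metadata must have columns {sorted(required)}, "
            f"got {list(metadata.columns)}"
        )
    if values.index.duplicated().any():
        dupes = sorted(set(values.index[values.index.duplicated()]))
        raise ValidationError(
            f"duplicate gene rows {dupes}; call collapse_probes explicitly"
        )
    return ExpressionMatrix(values=values, metadata=metadata)


def collapse_probes(
    values: pd.DataFrame, rule: str = "max_mean"
) -> pd.DataFrame:
    """Collapse duplicate gene rows to one row per gene.

    ``max_mean`` keeps the duplicate row with the highest mean intensity;
    ``median`` takes the elementwise median across duplicates.
    """
    if rule not in {"max_mean", "median"}:
        raise ValidationError(f"unknown collapse rule {rule!r}")
    if not values.index.duplicated().any():
        return values
    if rule == "median":
        collapsed = values.groupby(level=0, sort=False).median()
        return collapsed.loc[values.index.unique()]
    means = values.mean(axis=1).to_numpy()
    keep = np.zeros(len(values), dtype=bool)
    best: dict[str, tuple[float, int]] = {}
    for i, gene in enumerate(values.index):
        if gene not in best or means[i] > best[gene][0]:
            best[gene] = (means[i], i)
    for _, i in best.values():
        keep[i] = True
    return values.iloc[keep]


def welch_stats(
    case: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t-test over gene rows.

    Returns (lfc, p).  The squared standard error is floored at
    :data:`VARIANCE_FLOOR` so constant groups yield a finite statistic, and
    p-values are floored at :data:`P_FLOOR`.
    """
    n1, n2 = case.shape[1], reference.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs >= 2 samples")
    m1 = case.mean(axis=1)
    m2 = reference.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = reference.var(axis=1, ddof=1)
    se2 = np.maximum(v1 / n1 + v2 / n2, VARIANCE_FLOOR)
    t = (m1 - m2) / np.sqrt(se2)
    # Welch-Satterthwaite df; denominator guarded for constant groups
    num = se2**2
    den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    df = np.where(den > 0, num / np.maximum(den, 1e-300), n1 + n2 - 2)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, P_FLOOR, 1.0)
    return m1 - m2, p


def compute_gene_stats(
    matrix: ExpressionMatrix, contrast: ContrastSpec
) -> ContrastResult:
    """Per-gene lfc and Welch p-value for one contrast."""
    case_samples = matrix.group_samples(*contrast.case)
    ref_samples = matrix.group_samples(*contrast.reference)
    for name, samples in (("case", case_samples), ("reference", ref_samples)):
        if len(samples) < 2:
            raise ValidationError(
                f"contrast {contrast.label}: {name} group has "
                f"{len(samples)} sample(s); need >= 2"
            )
    if matrix.has_duplicate_genes():
        raise ValidationError("duplicate gene rows; collapse probes first")
    lfc, p = welch_stats(
        matrix.values[case_samples].to_numpy(),
        matrix.values[ref_samples].to_numpy(),
    )
    table = pd.DataFrame({"lfc": lfc, "p": p}, index=matrix.values.index)
    return ContrastResult(label=contrast.label, table=table)
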