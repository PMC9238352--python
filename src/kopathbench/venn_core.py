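"""Three-way Venn partition of per-contrast DEG sets and region ranking."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .deg_select import DegSet
from .errors import ValidationError

REGION_LABELS = (
    "A_only", "B_only", "C_only",
    "AB_only", "AC_only", "BC_only",
    "ABC",
)


@dataclass
class VennPartition:
    """The seven disjoint regions of three gene sets."""

    regions: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if set(self.regions) != set(REGION_LABELS):
            raise ValidationError(f"regions must be exactly {REGION_LABELS}")

    def __getitem__(self, label: str) -> frozenset[str]:
        return self.regions[label]

    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.regions.values():
            out |= genes
        return frozenset(out)


@dataclass
class RankedRegion:
    """Top-k genes of one region ordered by descending ranking key."""

    label: str
    genes: list[str]
    keys: list[float]


def venn_partition(
    degs_a: Iterable[str], degs_b: Iterable[str], degs_c: Iterable[str]
) -> VennPartition:
    """Exact set-algebra partition of three gene sets into seven regions."""
    a, b, c = set(degs_a), set(degs_b), set(degs_c)
    return VennPartition(regions={
        "ABC": frozenset(a & b & c),
        "AB_only": frozenset((a & b) - c),
        "AC_only": frozenset((a & c) - b),
        "BC_only": frozenset((b & c) - a),
        "A_only": frozenset(a - b - c),
        "B_only": frozenset(b - a - c),
        "C_only": frozenset(c - a - b),
    })


def rank_region(
    region: Iterable[str],
    deg_sets: Mapping[str, DegSet],
    k: int = 50,
    key: str = "best_edge_score",
) -> RankedRegion:
    """Rank a region's genes and keep the top k.

    The ranking key is the maximum best-edge-score over the contrasts in
    which the gene appears.  Ties break lexicographically by gene id.
    """
    if key != "best_edge_score":
        raise ValidationError(f"unsupported ranking key {key!r}")
    scored: list[tuple[float, str]] = []
    for gene in region:
        best = None
        for deg_set in deg_sets.values():
            if gene in deg_set.genes:
                value = float(deg_set.best_edge_score[gene])
                best = value if best is None else max(best, value)
        if best is None:
            raise ValidationError(
                f"gene {gene!r} is not present in any contributing DEG set"
            )
        scored.append((best, gene))
    scored.sort(key=lambda item: (-item[0], item[1]))
    top = scored[:k]
    return RankedRegion(
        label="", genes=[g for _, g in top], keys=[s for s, _ in top]
    )


def rank_all_regions(
    partition: VennPartition, deg_sets: Mapping[str, DegSet], k: int = 50
) -> dict[str, RankedRegion]:
    out: dict[str, RankedRegion] = {}
    for label in REGION_LABELS:
        ranked = rank_region(partition[label], deg_sets, k=k)
        ranked.label = label
        out[label] = ranked
    return out


def core_union_count(partition: VennPartition, selection: Iterable[str]) -> int:
    """Number of distinct genes in the union of the selected regions."""
    count: set[str] = set()
    for label in selection:
        if label not in REGION_LABELS:
            raise ValidationError(f"unknown region label {label!r}")
        count |= partition[label]
    return len(count)


def write_venn_tsv(
    ranked: Mapping[str, RankedRegion], path: str | Path
) -> None:
    """TSV with columns region, rank, gene, key."""
    lines = ["region\trank\tgene\tkey"]
    for label in REGION_LABELS:
        region = ranked[label]
        for i, (gene, key) in enumerate(zip(region.genes, region.keys), start=1):
            lines.append(f"{label}\t{i}\t{gene}\t{key:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")
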