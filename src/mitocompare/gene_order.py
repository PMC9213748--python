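"""Circular signed gene orders and breakpoint distances between them.

Orders are signed (strand-aware) circular sequences compared up to rotation
only — a whole-molecule reflection is a real rearrangement here, not a
normalization, because strand is biologically meaningful in these genomes.
The breakpoint distance is the number of signed adjacencies present in one
order but not the other after both are restricted to their shared gene set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .mito_io import CANONICAL_GENE_ORDER, MitoGenome

SignedGene = tuple[str, int]


@dataclass(frozen=True)
class GeneOrder:
    genome_id: str
    genes: tuple[SignedGene, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty gene order")
        names = [g for g, _ in self.genes]
        dups = {n for n in names if names.count(n) > 1}
        if dups:
            raise ValueError(f"duplicate gene labels: {sorted(dups)}")

    def labels(self) -> list[str]:
        return [f"{'-' if s == -1 else ''}{g}" for g, s in self.genes]

    def restrict(self, keep: set[str]) -> "GeneOrder":
        return GeneOrder(self.genome_id, tuple((g, s) for g, s in self.genes if g in keep))


@dataclass(frozen=True)
class BreakpointResult:
    genome_a: str
    genome_b: str
    shared_genes: int
    breakpoints: int
    identical: bool


CANONICAL_ORDER = GeneOrder("canonical", tuple((g, 1) for g in CANONICAL_GENE_ORDER))


def extract_gene_order(genome: MitoGenome) -> GeneOrder:
    """Signed circular order of all annotated features, sorted by start."""
    return GeneOrder(genome.id, tuple((f.name, f.strand) for f in genome.features))


def _adjacencies(order: GeneOrder) -> set[tuple[SignedGene, SignedGene]]:
    """Directed signed adjacency set of a circular order (rotation-invariant)."""
    n = len(order.genes)
    return {(order.genes[i], order.genes[(i + 1) % n]) for i in range(n)}


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> BreakpointResult:
    """Signed circular breakpoint count between two orders on their shared genes."""
    shared = {g for g, _ in a.genes} & {g for g, _ in b.genes}
    if len(shared) < 2:
        raise ValueError(f"shared gene set too small ({len(shared)}) for a comparison")
    ra, rb = a.restrict(shared), b.restrict(shared)
    adj_a, adj_b = _adjacencies(ra), _adjacencies(rb)
    bp = len(adj_a - adj_b)
    return BreakpointResult(a.genome_id, b.genome_id, len(shared), bp, bp == 0)


def pairwise_breakpoints(orders: list[GeneOrder]) -> pd.DataFrame:
    rows = []
    for i in range(len(orders)):
        for j in range(i + 1, len(orders)):
            r = breakpoint_distance(orders[i], orders[j])
            rows.append(r.__dict__)
    return pd.DataFrame(
        rows, columns=["genome_a", "genome_b", "shared_genes", "breakpoints", "identical"]
    )


def order_map(orders: list[GeneOrder], anchor: str = "ND5") -> pd.DataFrame:
    """Linear rendering of each circular order, rotated to start at ``anchor``.

    Genomes missing the anchor fall back to their first gene with a warning.
    One row per genome; column ``pos_k`` holds the signed label at position k.
    """
    rows = []
    width = max(len(o.genes) for o in orders)
    for o in orders:
        names = [g for g, _ in o.genes]
        if anchor in names:
            k = names.index(anchor)
        else:
            warnings.warn(f"{o.genome_id}: anchor {anchor} absent; starting at first gene")
            k = 0
        rotated = o.genes[k:] + o.genes[:k]
        labels = GeneOrder(o.genome_id, rotated).labels()
        rows.append({"genome": o.genome_id,
                     **{f"pos_{i}": (labels[i] if i < len(labels) else "") for i in range(width)}})
    return pd.DataFrame(rows)


__all__ = [
    "GeneOrder", "BreakpointResult", "CANONICAL_ORDER",
    "extract_gene_order", "breakpoint_distance", "pairwise_breakpoints", "order_map",
]
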