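"""Base composition, AT/GC skew, intergenic accounting, and the G(A)nT motif scan.

Skews follow the standard definitions
``AT skew = (A - T)/(A + T)`` and ``GC skew = (G - C)/(G + C)``,
computed on the coding (extracted) strand for annotated genes.  N bases are
counted but excluded from every percentage and skew denominator.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import pandas as pd

from .mito_io import (
    CANONICAL_PCGS,
    CANONICAL_RRNAS,
    MitoGenome,
    extract_feature_sequence,
)

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class BaseComposition:
    a: int
    t: int
    g: int
    c: int
    n: int

    @property
    def length(self) -> int:
        return self.a + self.t + self.g + self.c + self.n

    @property
    def acgt(self) -> int:
        return self.a + self.t + self.g + self.c

    @property
    def at_percent(self) -> float:
        """A+T as a percentage of unambiguous bases; NaN when all-N."""
        if self.acgt == 0:
            return float("nan")
        return 100.0 * (self.a + self.t) / self.acgt

    @property
    def gc_percent(self) -> float:
        if self.acgt == 0:
            return float("nan")
        return 100.0 * (self.g + self.c) / self.acgt

    def __add__(self, other: "BaseComposition") -> "BaseComposition":
        return BaseComposition(
            self.a + other.a, self.t + other.t, self.g + other.g,
            self.c + other.c, self.n + other.n,
        )


@dataclass(frozen=True)
class SkewRecord:
    scope: str  # whole_genome | PCGs | rRNAs | gene:<name>
    at_skew: float
    gc_skew: float
    at_undefined: bool = False
    gc_undefined: bool = False
    missing: bool = False


@dataclass(frozen=True)
class IntergenicRegion:
    start: int  # 0-based on the circle
    end: int    # half-open; may exceed genome length on a wrapping region
    length: int
    flanking_upstream: str
    flanking_downstream: str


@dataclass(frozen=True)
class MotifHit:
    start: int
    run_length: int
    context_region: IntergenicRegion | None = None


def count_bases(seq: str) -> BaseComposition:
    """Exact base counts; alphabet restricted to A/C/G/T/N."""
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"unsupported characters in sequence: {sorted(bad)}")
    return BaseComposition(
        seq.count("A"), seq.count("T"), seq.count("G"), seq.count("C"), seq.count("N")
    )


def compute_skew(comp: BaseComposition, scope: str = "whole_genome") -> SkewRecord:
    at_den = comp.a + comp.t
    gc_den = comp.g + comp.c
    at = (comp.a - comp.t) / at_den if at_den else 0.0
    gc = (comp.g - comp.c) / gc_den if gc_den else 0.0
    return SkewRecord(scope, at, gc, at_undefined=at_den == 0, gc_undefined=gc_den == 0)


def _skew_row(genome_id: str, scope: str, comp: BaseComposition) -> dict:
    rec = compute_skew(comp, scope)
    return {
        "genome": genome_id, "scope": rec.scope,
        "A": comp.a, "T": comp.t, "G": comp.g, "C": comp.c, "N": comp.n,
        "at_percent": comp.at_percent, "gc_percent": comp.gc_percent,
        "at_skew": rec.at_skew, "gc_skew": rec.gc_skew,
        "at_undefined": rec.at_undefined, "gc_undefined": rec.gc_undefined,
        "missing": False,
    }


def per_gene_skew_table(genomes: list[MitoGenome]) -> pd.DataFrame:
    """Composition and skew per gene plus whole-genome / PCGs / rRNAs aggregates.

    Gene sequences are measured on the coding strand.  The PCGs aggregate is
    the concatenation of the 13 protein-coding genes in canonical label order,
    stop codons included; missing canonical genes yield flagged rows.
    """
    rows = []
    for g in genomes:
        rows.append(_skew_row(g.id, "whole_genome", count_bases(g.sequence)))
        for scope, names in (("PCGs", CANONICAL_PCGS), ("rRNAs", CANONICAL_RRNAS)):
            agg = BaseComposition(0, 0, 0, 0, 0)
            for name in names:
                f = g.get_feature(name)
                if f is not None:
                    agg = agg + count_bases(extract_feature_sequence(g, f))
            rows.append(_skew_row(g.id, scope, agg))
        for name in (*CANONICAL_PCGS, *CANONICAL_RRNAS):
            f = g.get_feature(name)
            if f is None:
                rows.append({
                    "genome": g.id, "scope": f"gene:{name}",
                    "A": 0, "T": 0, "G": 0, "C": 0, "N": 0,
                    "at_percent": float("nan"), "gc_percent": float("nan"),
                    "at_skew": float("nan"), "gc_skew": float("nan"),
                    "at_undefined": True, "gc_undefined": True, "missing": True,
                })
            else:
                rows.append(
                    _skew_row(g.id, f"gene:{name}", count_bases(extract_feature_sequence(g, f)))
                )
    return pd.DataFrame(rows)


def extract_intergenic(genome: MitoGenome) -> list[IntergenicRegion]:
    """Maximal unannotated runs on the circle, with flanking gene labels.

    Overlapping annotations are tolerated (the overlap is simply covered);
    a warning is emitted because mitogenome annotations here are expected to
    be non-overlapping.
    """
    n = len(genome)
    owner = [None] * n  # feature covering each position (last writer wins)
    covered_twice = False
    for f in genome.features:
        for p in range(f.start, f.end):
            q = p % n
            if owner[q] is not None:
                covered_twice = True
            owner[q] = f
    if covered_twice:
        warnings.warn(f"{genome.id}: overlapping features; overlap assigned to later feature")
    if all(o is not None for o in owner):
        return []
    if all(o is None for o in owner):
        return [IntergenicRegion(0, n, n, "", "")]
    # walk the circle starting just after a covered position
    start0 = next(i for i in range(n) if owner[i] is not None)
    regions: list[IntergenicRegion] = []
    i = start0
    seen = 0
    while seen < n:
        if owner[i % n] is None:
            s = i
            while seen < n and owner[i % n] is None:
                i += 1
                seen += 1
            up = owner[(s - 1) % n]
            down = owner[i % n]
            regions.append(
                IntergenicRegion(s % n, (s % n) + (i - s), i - s,
                                 up.name if up else "", down.name if down else "")
            )
        else:
            i += 1
            seen += 1
    return sorted(regions, key=lambda r: r.start)


def total_ign(genome: MitoGenome) -> tuple[int, int, IntergenicRegion | None]:
    """(total intergenic bp, number of regions, longest region)."""
    regions = extract_intergenic(genome)
    if not regions:
        return 0, 0, None
    longest = max(regions, key=lambda r: r.length)
    return sum(r.length for r in regions), len(regions), longest


def find_cr_motif(seq: str, min_run: int = 3, circular: bool = False) -> list[MotifHit]:
    """All non-overlapping maximal G·A^k·T matches with k >= min_run.

    On circular input the scan continues across the origin; hits are reported
    by their start position modulo the sequence length.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    n = len(seq)
    pattern = re.compile(f"G(A{{{min_run},}})T")
    scan = seq + (seq[: min(n, min_run + 2)] if circular and n else "")
    hits = []
    seen_starts = set()
    for m in pattern.finditer(scan):
        start = m.start() % n if n else m.start()
        if start in seen_starts:
            continue
        if m.start() >= n:  # wholly inside the appended copy
            continue
        seen_starts.add(start)
        hits.append(MotifHit(start=start, run_length=len(m.group(1))))
    return hits


def scan_genome_motifs(genome: MitoGenome, min_run: int = 3) -> list[MotifHit]:
    """CR-motif scan over the whole circle, tagging hits inside intergenic regions."""
    regions = extract_intergenic(genome)
    hits = find_cr_motif(genome.sequence, min_run=min_run, circular=genome.circular)
    n = len(genome)
    out = []
    for h in hits:
        ctx = None
        for r in regions:
            span = range(r.start, r.end)
            if h.start in {p % n for p in span}:
                ctx = r
                break
        out.append(MotifHit(h.start, h.run_length, ctx))
    return out


__all__ = [
    "BaseComposition", "SkewRecord", "IntergenicRegion", "MotifHit",
    "count_bases", "compute_skew", "per_gene_skew_table",
    "extract_intergenic", "total_ign", "find_cr_motif", "scan_genome_motifs",
]
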