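"""Reading and writing annotated mitogenomes.

Coordinate contract used by every module in this package:

* internal coordinates are 0-based, half-open ``[start, end)``;
* all files use the 1-based inclusive GenBank dialect;
* on a circular molecule a feature may wrap the origin, represented by
  ``end > len(genome)`` (modular arithmetic on the circle);
* strand is +1 or -1; ``extract_feature_sequence`` returns the coding
  (reverse-complemented) sequence for -1 features.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation

CANONICAL_PCGS = (
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "cox1", "cox2", "cox3", "cob", "atp6", "atp8",
)
CANONICAL_RRNAS = ("s-rRNA", "l-rRNA")
CANONICAL_TRNAS = ("trnW", "trnM")

#: gene order of the focal anemone mitogenome, shared by most Actiniaria
CANONICAL_GENE_ORDER = (
    "ND5", "ND1", "ND3", "trnW", "ND2", "s-rRNA", "cox2", "ND4",
    "ND6", "cob", "trnM", "l-rRNA", "cox3", "cox1", "ND4L", "atp8", "atp6",
)

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MitoParseError(ValueError):
    """Raised on malformed input files."""


def _load_synonym_map() -> dict[str, str]:
    path = resources.files("mitocompare").joinpath("data/gene_synonyms.tsv")
    table: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        alias, canonical = line.split("\t")
        table[alias.lower()] = canonical
    return table


_SYNONYMS: dict[str, str] | None = None


def normalize_gene_name(name: str) -> str:
    """Map a gene label to its canonical form; unknown labels pass through."""
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = _load_synonym_map()
    return _SYNONYMS.get(name.strip().lower(), name.strip())


@dataclass(frozen=True)
class GeneFeature:
    """An annotated feature on a (possibly circular) mitogenome.

    ``end`` may exceed the genome length to denote an origin-wrapping span.
    """

    name: str
    kind: str  # CDS | rRNA | tRNA | other
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: int = 1
    length_warning: bool = False  # CDS whose length is not divisible by 3

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"feature {self.name}: end {self.end} <= start {self.start}")
        if self.strand not in (1, -1):
            raise ValueError(f"feature {self.name}: strand must be +1/-1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MitoGenome:
    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    depth_class: str = "unknown"  # deep | shallow | unknown

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise MitoParseError(
                f"{self.id}: ambiguity codes other than N are not supported: {sorted(bad)}"
            )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        n = len(self.sequence)
        for f in self.features:
            if f.length > n:
                raise ValueError(f"feature {f.name} longer than genome")
            if f.start < 0 or f.start >= n:
                raise ValueError(f"feature {f.name} start outside [0, {n})")
            if f.end > n and not self.circular:
                raise ValueError(f"wrapping feature {f.name} on a linear genome")

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, kind: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == kind]

    def get_feature(self, name: str) -> GeneFeature | None:
        for f in self.features:
            if f.name == name:
                return f
        return None


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_feature_sequence(genome: MitoGenome, feature: GeneFeature) -> str:
    """Extracted coding-strand sequence of a feature (wraps the circle if needed)."""
    n = len(genome)
    if feature.end <= n:
        seq = genome.sequence[feature.start:feature.end]
    else:
        if not genome.circular:
            raise ValueError(f"wrapping feature {feature.name} on a linear genome")
        seq = genome.sequence[feature.start:] + genome.sequence[: feature.end - n]
    if feature.strand == -1:
        seq = reverse_complement(seq)
    return seq


def _kind_of(bio_type: str) -> str:
    return {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA"}.get(bio_type, "other")


def _feature_name(bf) -> str:
    for key in ("gene", "product", "locus_tag", "label"):
        if key in bf.qualifiers:
            return normalize_gene_name(bf.qualifiers[key][0])
    return f"{bf.type}@{int(bf.location.start)}"


def read_genbank(path: str | Path, depth_class: str = "unknown") -> MitoGenome:
    """Read a GenBank flat file into the internal 0-based representation.

    ``join`` locations that run across the origin of a circular record become
    a single wrapping span (end > genome length).
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise MitoParseError(f"{path}: malformed GenBank record: {exc}") from exc
    n = len(record.seq)
    circular = record.annotations.get("topology", "linear") == "circular"
    feats: list[GeneFeature] = []
    for bf in record.features:
        kind = _kind_of(bf.type)
        if bf.type in ("source", "gene"):
            continue
        if kind == "other" and bf.type not in ("misc_feature", "D-loop"):
            continue
        loc = bf.location
        strand = -1 if loc.strand == -1 else 1
        if isinstance(loc, CompoundLocation):
            parts = sorted(loc.parts, key=lambda p: int(p.start))
            # join across origin: last part ends at n, first begins at 0
            if len(parts) == 2 and int(parts[1].end) == n and int(parts[0].start) == 0:
                start, end = int(parts[1].start), n + int(parts[0].end)
            else:
                start, end = int(parts[0].start), int(parts[-1].end)
        else:
            start, end = int(loc.start), int(loc.end)
        warn = kind == "CDS" and (end - start) % 3 != 0
        if warn:
            warnings.warn(f"{path.name}: CDS {_feature_name(bf)} length not divisible by 3")
        feats.append(GeneFeature(_feature_name(bf), kind, start, end, strand, warn))
    return MitoGenome(
        id=record.id or path.stem,
        sequence=str(record.seq).upper(),
        circular=circular,
        features=feats,
        depth_class=depth_class,
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """id -> uppercase sequence for every record in a FASTA file."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_feature_table(
    fasta: str | Path, table: str | Path, circular: bool = True,
    depth_class: str = "unknown",
) -> MitoGenome:
    """Build a MitoGenome from a FASTA plus a TSV feature table.

    Table columns (1-based inclusive coordinates, as in GenBank):
    ``name  kind  start  end  strand``.  ``end < start`` on a circular genome
    denotes a span wrapping the origin.
    """
    seqs = read_fasta(fasta)
    if len(seqs) != 1:
        raise MitoParseError(f"{fasta}: expected exactly one FASTA record")
    (gid, seq), = seqs.items()
    n = len(seq)
    feats: list[GeneFeature] = []
    df = pd.read_csv(table, sep="\t", comment="#", dtype=str)
    required = {"name", "kind", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise MitoParseError(f"{table}: need columns {sorted(required)}")
    for _, row in df.iterrows():
        start1, end1 = int(row["start"]), int(row["end"])
        strand = -1 if str(row["strand"]) in ("-", "-1") else 1
        if end1 >= start1:
            start, end = start1 - 1, end1
        else:  # wraps the origin
            if not circular:
                raise MitoParseError(f"{table}: wrapping feature {row['name']} on linear genome")
            start, end = start1 - 1, n + end1
        kind = row["kind"]
        warn = kind == "CDS" and (end - start) % 3 != 0
        feats.append(GeneFeature(normalize_gene_name(row["name"]), kind, start, end, strand, warn))
    _warn_overlaps(feats, n)
    return MitoGenome(gid, seq, circular, feats, depth_class)


def _warn_overlaps(feats: Iterable[GeneFeature], n: int) -> None:
    covered: set[int] = set()
    for f in sorted(feats, key=lambda f: f.start):
        span = {p % n for p in range(f.start, f.end)}
        if covered & span:
            warnings.warn(f"feature {f.name} overlaps a previous feature")
        covered |= span


def write_feature_table(genome: MitoGenome, path: str | Path) -> None:
    """Inverse of read_feature_table (1-based inclusive, wrap as end < start)."""
    n = len(genome)
    rows = []
    for f in genome.features:
        if f.end <= n:
            start1, end1 = f.start + 1, f.end
        else:
            start1, end1 = f.start + 1, f.end - n
        rows.append((f.name, f.kind, start1, end1, "+" if f.strand == 1 else "-"))
    pd.DataFrame(rows, columns=["name", "kind", "start", "end", "strand"]).to_csv(
        path, sep="\t", index=False
    )


def write_report_tables(results: pd.DataFrame, out_dir: str | Path, stem: str) -> tuple[Path, Path]:
    """Write a result table as TSV plus a JSON mirror; deterministic row order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / f"{stem}.tsv"
    js = out_dir / f"{stem}.json"
    results.to_csv(tsv, sep="\t", index=False, float_format="%.4f")
    js.write_text(json.dumps(results.to_dict(orient="records"), indent=1, default=str))
    return tsv, js


def translate_sequence(seq: str) -> Seq:  # thin Biopython passthrough for callers
    return Seq(seq)


__all__ = [
    "MitoGenome", "GeneFeature", "MitoParseError",
    "CANONICAL_PCGS", "CANONICAL_RRNAS", "CANONICAL_TRNAS", "CANONICAL_GENE_ORDER",
    "read_genbank", "read_feature_table", "read_fasta", "write_fasta",
    "write_feature_table", "write_report_tables",
    "extract_feature_sequence", "reverse_complement", "normalize_gene_name",
]
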