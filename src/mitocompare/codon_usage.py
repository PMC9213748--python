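"""Codon counting, RSCU, start/stop auditing and depth-group amino-acid contrasts.

The default genetic code is NCBI translation table 4 (mold / protozoan /
coelenterate mitochondrial): stops are TAA and TAG, and TGA encodes Trp.
RSCU for a codon is its count divided by the mean count over its synonymous
family, so an unbiased family has RSCU 1 for every member and the family's
RSCU values sum to its degeneracy.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .mito_io import MitoGenome, extract_feature_sequence

STOP = "*"

#: residue classes used for the depth-group profile comparison
AA_CLASSES = {
    "nonpolar": frozenset("GAVLIPFMW"),
    "polar_uncharged": frozenset("STCYNQ"),
    "charged": frozenset("DEKRH"),
}
AMINO_ACIDS = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))

_BASES = "ACGT"


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino-acid map with an explicit stop symbol and start set."""

    table_id: int
    codon_map: dict[str, str]
    start_codons: frozenset[str]

    @classmethod
    def from_table_id(cls, table_id: int = 4) -> "GeneticCode":
        tbl = CodonTable.unambiguous_dna_by_id[table_id]
        cmap = {c.upper(): aa for c, aa in tbl.forward_table.items()}
        for stop in tbl.stop_codons:
            cmap[stop.upper()] = STOP
        assert len(cmap) == 64
        return cls(table_id, cmap, frozenset(s.upper() for s in tbl.start_codons))

    def translate_codon(self, codon: str) -> str:
        return self.codon_map[codon.upper()]

    def is_stop(self, codon: str) -> bool:
        return self.codon_map.get(codon.upper()) == STOP

    def synonymous_families(self) -> dict[str, list[str]]:
        """amino acid -> sorted list of its sense codons."""
        fams: dict[str, list[str]] = {}
        for codon, aa in sorted(self.codon_map.items()):
            if aa == STOP:
                continue
            fams.setdefault(aa, []).append(codon)
        return fams


@dataclass
class CodonUsageTable:
    code: GeneticCode
    counts: dict[str, int] = field(default_factory=dict)        # sense codons only
    stop_counts: dict[str, int] = field(default_factory=dict)   # terminal stops
    skipped_codons: int = 0                                     # contained N
    rscu: dict[str, float] = field(default_factory=dict)

    @property
    def total_codons(self) -> int:
        """Sense codons counted (stop codons excluded)."""
        return sum(self.counts.values())

    @property
    def total_with_stops(self) -> int:
        return self.total_codons + sum(self.stop_counts.values())

    def aa_counts(self) -> dict[str, int]:
        out = {aa: 0 for aa in AMINO_ACIDS}
        for codon, k in self.counts.items():
            out[self.code.translate_codon(codon)] += k
        return out

    def aa_percentages(self) -> dict[str, float]:
        total = self.total_codons
        if total == 0:
            return {aa: float("nan") for aa in AMINO_ACIDS}
        return {aa: 100.0 * k / total for aa, k in self.aa_counts().items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "codon": c,
                "amino_acid": self.code.translate_codon(c),
                "count": self.counts.get(c, 0),
                "rscu": self.rscu.get(c, float("nan")),
            }
            for c in sorted(self.code.codon_map)
            if not self.code.is_stop(c)
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class AminoAcidProfile:
    genome_id: str
    aa_percent: dict[str, float]
    class_percent: dict[str, float]


@dataclass(frozen=True)
class GroupComparisonResult:
    label: str
    mean_deep: float
    sd_deep: float
    mean_shallow: float
    sd_shallow: float
    t: float
    p: float
    p_bonferroni: float
    n_deep: int
    n_shallow: int
    flag: str = ""


def audit_start_stop(genome: MitoGenome, code: GeneticCode | None = None) -> pd.DataFrame:
    """First and last codon of every CDS, with non-ATG / non-stop flags."""
    code = code or GeneticCode.from_table_id(4)
    rows = []
    for f in genome.features_of_kind("CDS"):
        seq = extract_feature_sequence(genome, f)
        if len(seq) % 3 != 0:
            rows.append({
                "genome": genome.id, "gene": f.name, "start_codon": "", "stop_codon": "",
                "start_is_atg": False, "stop_is_stop": False, "flag": "length_not_multiple_of_3",
            })
            continue
        start, stop = seq[:3], seq[-3:]
        rows.append({
            "genome": genome.id, "gene": f.name,
            "start_codon": start, "stop_codon": stop,
            "start_is_atg": start == "ATG", "stop_is_stop": code.is_stop(stop),
            "flag": "",
        })
    return pd.DataFrame(rows)


def split_codons(seq: str) -> list[str]:
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


def count_codons(
    cds_sequences: list[str], code: GeneticCode | None = None
) -> CodonUsageTable:
    """Pool codon counts over CDS sequences.

    Stop codons are tallied separately and excluded from usage statistics;
    codons containing N are skipped and counted in ``skipped_codons``.
    """
    code = code or GeneticCode.from_table_id(4)
    table = CodonUsageTable(code=code)
    for seq in cds_sequences:
        for codon in split_codons(seq.upper()):
            if "N" in codon:
                table.skipped_codons += 1
            elif code.is_stop(codon):
                table.stop_counts[codon] = table.stop_counts.get(codon, 0) + 1
            else:
                table.counts[codon] = table.counts.get(codon, 0) + 1
    return table


def compute_rscu(table: CodonUsageTable) -> CodonUsageTable:
    """Fill RSCU: count / family-mean count; unexpressed families stay NaN."""
    for aa, family in table.code.synonymous_families().items():
        total = sum(table.counts.get(c, 0) for c in family)
        if total == 0:
            for c in family:
                table.rscu[c] = float("nan")
            continue
        mean = total / len(family)
        for c in family:
            table.rscu[c] = table.counts.get(c, 0) / mean
    return table


def amino_acid_profile(table: CodonUsageTable, genome_id: str) -> AminoAcidProfile:
    aa_pct = table.aa_percentages()
    class_pct = {
        cls: sum(aa_pct[a] for a in members if a in aa_pct)
        for cls, members in AA_CLASSES.items()
    }
    return AminoAcidProfile(genome_id, aa_pct, class_pct)


def genome_codon_usage(genome: MitoGenome, code: GeneticCode | None = None) -> CodonUsageTable:
    """Codon usage pooled over all in-frame CDS features of one genome."""
    code = code or GeneticCode.from_table_id(4)
    seqs = [
        extract_feature_sequence(genome, f)
        for f in genome.features_of_kind("CDS")
        if (f.length % 3) == 0
    ]
    return compute_rscu(count_codons(seqs, code))


def _welch_row(label: str, deep: np.ndarray, shallow: np.ndarray, n_tests: int) -> GroupComparisonResult:
    flag = ""
    if len(deep) < 2 or len(shallow) < 2:
        return GroupComparisonResult(
            label,
            float(np.mean(deep)) if len(deep) else float("nan"),
            float(np.std(deep, ddof=1)) if len(deep) > 1 else float("nan"),
            float(np.mean(shallow)) if len(shallow) else float("nan"),
            float(np.std(shallow, ddof=1)) if len(shallow) > 1 else float("nan"),
            float("nan"), float("nan"), float("nan"),
            len(deep), len(shallow), flag="untestable_group_size",
        )
    if len(deep) < 3 or len(shallow) < 3:
        flag = "small_group"
    if np.isclose(np.mean(deep), np.mean(shallow)):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(deep, shallow, equal_var=False)
        t, p = float(t), float(p)
    return GroupComparisonResult(
        label,
        float(np.mean(deep)), float(np.std(deep, ddof=1)),
        float(np.mean(shallow)), float(np.std(shallow, ddof=1)),
        t, p, min(1.0, p * n_tests), len(deep), len(shallow), flag,
    )


def compare_depth_groups(
    profiles: list[AminoAcidProfile], grouping: dict[str, str]
) -> pd.DataFrame:
    """Welch two-sided t-tests of deep vs shallow amino-acid usage.

    One row per amino acid (20) and per residue class (3).  No multiple-testing
    correction is applied to ``p``; a Bonferroni column is emitted alongside
    for transparency.
    """
    deep = [p for p in profiles if grouping.get(p.genome_id) == "deep"]
    shallow = [p for p in profiles if grouping.get(p.genome_id) == "shallow"]
    if min(len(deep), len(shallow)) < 3:
        warnings.warn("a depth group has fewer than 3 members; t-tests are fragile")
    rows = []
    for aa in AMINO_ACIDS:
        d = np.array([p.aa_percent[aa] for p in deep])
        s = np.array([p.aa_percent[aa] for p in shallow])
        rows.append(_welch_row(aa, d, s, n_tests=len(AMINO_ACIDS)))
    for cls in AA_CLASSES:
        d = np.array([p.class_percent[cls] for p in deep])
        s = np.array([p.class_percent[cls] for p in shallow])
        rows.append(_welch_row(cls, d, s, n_tests=len(AA_CLASSES)))
    return pd.DataFrame([r.__dict__ for r in rows])


def all_codons() -> list[str]:
    return ["".join(c) for c in itertools.product(_BASES, repeat=3)]


__all__ = [
    "GeneticCode", "CodonUsageTable", "AminoAcidProfile", "GroupComparisonResult",
    "AA_CLASSES", "AMINO_ACIDS", "STOP",
    "audit_start_stop", "count_codons", "compute_rscu", "amino_acid_profile",
    "genome_codon_usage", "compare_depth_groups", "split_codons", "all_codons",
]
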