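"""Synthetic annotated mitogenomes and evolved families with known ground truth.

The default configuration emulates a typical actiniarian mitogenome: a
circular ~16.6 kb molecule carrying 13 protein-coding genes, two tRNAs and
two rRNAs in the canonical gene order, everything on the heavy strand,
negative AT skew and positive GC skew, 17 intergenic spacers (the longest
between ND5 and ND1, and a 147 bp spacer between s-rRNA and cox2 carrying an
embedded G(A)nT control-region-like motif).

Composition targets are met by quota (largest-remainder) sampling of bases
and codons rather than iid draws, so a 16 kb genome realizes its configured
skews to within a few thousandths; the random seed then only shuffles the
arrangement.  Families are evolved on a star tree: per-site substitution
proposals arrive at ``branch_length x gene rate multiplier`` per site; inside
a CDS a proposal that would create a stop codon is rejected, a nonsynonymous
proposal is accepted with probability ``omega``, and a synonymous proposal is
always accepted.  Start and stop codons are frozen.  No indels are simulated,
so per-gene alignments are trivially the extracted gene sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codon_usage import GeneticCode, all_codons, split_codons
from .diversity import Alignment
from .mito_io import (
    CANONICAL_GENE_ORDER,
    GeneFeature,
    MitoGenome,
    extract_feature_sequence,
    write_fasta,
    write_feature_table,
)

_BASES = "ACGT"

#: (name, kind, length) in canonical order; lengths typical for sea anemones.
DEFAULT_GENE_PLAN: tuple[tuple[str, str, int], ...] = (
    ("ND5", "CDS", 1839),
    ("ND1", "CDS", 984),
    ("ND3", "CDS", 351),
    ("trnW", "tRNA", 71),
    ("ND2", "CDS", 1380),
    ("s-rRNA", "rRNA", 1055),
    ("cox2", "CDS", 741),
    ("ND4", "CDS", 1479),
    ("ND6", "CDS", 591),
    ("cob", "CDS", 1158),
    ("trnM", "tRNA", 71),
    ("l-rRNA", "rRNA", 2162),
    ("cox3", "CDS", 786),
    ("cox1", "CDS", 1578),
    ("ND4L", "CDS", 300),
    ("atp8", "CDS", 219),
    ("atp6", "CDS", 699),
)

#: spacer after each gene in DEFAULT_GENE_PLAN (17 junctions, 1112 bp total);
#: 223 bp after ND5 and a 147 bp motif-bearing spacer after s-rRNA.
DEFAULT_SPACER_PLAN: tuple[int, ...] = (
    223, 55, 40, 38, 52, 147, 60, 48, 45, 50, 42, 58, 47, 53, 44, 50, 60
)


@dataclass(frozen=True)
class TipSpec:
    """One terminal branch of the (star) tree a family is evolved on."""

    name: str
    branch_length: float          # expected substitution proposals per site
    omega: float = 1.0            # acceptance probability of nonsynonymous proposals
    depth_class: str = "unknown"


@dataclass
class SimConfig:
    seed: int = 0
    gene_plan: tuple[tuple[str, str, int], ...] = DEFAULT_GENE_PLAN
    spacer_plan: tuple[int, ...] = DEFAULT_SPACER_PLAN
    at_percent: float = 62.4
    at_skew: float = -0.12
    gc_skew: float = 0.121
    per_gene_targets: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    motif_spacer_index: int = 5   # junction after s-rRNA (-> cox2)
    motif_run: int = 5            # A-run length of the embedded G(A)nT
    table_id: int = 4
    tips: tuple[TipSpec, ...] = ()
    rate_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.spacer_plan) != len(self.gene_plan):
            raise ValueError("need one spacer per gene junction")
        for name, kind, length in self.gene_plan:
            if kind == "CDS" and length % 3 != 0:
                raise ValueError(f"CDS {name} length {length} not divisible by 3")
        for tgt in (self.at_skew, self.gc_skew, *(
            v for t in self.per_gene_targets.values() for v in t[1:]
        )):
            if abs(tgt) > 1:
                raise ValueError(f"infeasible skew target {tgt}")

    def targets_for(self, gene: str) -> tuple[float, float, float]:
        return self.per_gene_targets.get(gene, (self.at_percent, self.at_skew, self.gc_skew))


@dataclass
class SimTruth:
    """Everything a test needs to check analysis output against the generator."""

    seed: int
    composition: dict[str, dict[str, int]] = field(default_factory=dict)  # region -> base counts
    codon_counts: dict[str, dict[str, int]] = field(default_factory=dict)  # gene -> codon counts
    motif: dict | None = None  # {"spacer_start":..., "offset":..., "run_length":...}
    tips: list[dict] = field(default_factory=list)
    rate_multipliers: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)


def _base_probs(at_percent: float, at_skew: float, gc_skew: float) -> np.ndarray:
    at = at_percent / 100.0
    return np.array([
        at * (1 + at_skew) / 2,        # A
        (1 - at) * (1 - gc_skew) / 2,  # C
        (1 - at) * (1 + gc_skew) / 2,  # G
        at * (1 - at_skew) / 2,        # T
    ])


def _quota_counts(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` items to ``weights``."""
    w = weights / weights.sum()
    raw = w * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _sample_bases(length: int, probs: np.ndarray, rng: np.random.Generator) -> str:
    counts = _quota_counts(probs, length)
    pool = np.repeat(np.frombuffer(_BASES.encode(), dtype=np.uint8), counts)
    rng.shuffle(pool)
    return pool.tobytes().decode()


def _sample_cds(
    length: int, probs: np.ndarray, code: GeneticCode,
    rng: np.random.Generator, stop: str,
) -> str:
    """ATG + quota-sampled interior sense codons + the requested stop codon."""
    ncod = length // 3
    interior = ncod - 2
    codons = all_codons()
    p = {b: probs[i] for i, b in enumerate(_BASES)}
    weights = np.array([
        0.0 if code.is_stop(c) else p[c[0]] * p[c[1]] * p[c[2]] for c in codons
    ])
    counts = _quota_counts(weights, interior)
    pool = [c for c, k in zip(codons, counts) for _ in range(k)]
    rng.shuffle(pool)
    return "ATG" + "".join(pool) + stop


def _count(seq: str) -> dict[str, int]:
    return {b: seq.count(b) for b in _BASES}


def generate_ancestor(cfg: SimConfig) -> tuple[MitoGenome, SimTruth]:
    """Build the annotated ancestral genome; byte-identical under a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    code = GeneticCode.from_table_id(cfg.table_id)
    truth = SimTruth(seed=cfg.seed, rate_multipliers=dict(cfg.rate_multipliers))
    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for i, (name, kind, length) in enumerate(cfg.gene_plan):
        probs = _base_probs(*cfg.targets_for(name))
        if kind == "CDS":
            stop = "TAG" if name == "ND3" else "TAA"
            seq = _sample_cds(length, probs, code, rng, stop)
            truth.codon_counts[name] = {}
            for codon in split_codons(seq):
                truth.codon_counts[name][codon] = truth.codon_counts[name].get(codon, 0) + 1
        else:
            seq = _sample_bases(length, probs, rng)
        features.append(GeneFeature(name, kind, pos, pos + length, 1))
        truth.composition[name] = _count(seq)
        parts.append(seq)
        pos += length
        spacer_len = cfg.spacer_plan[i]
        spacer = _sample_bases(spacer_len, _base_probs(cfg.at_percent, cfg.at_skew, cfg.gc_skew), rng)
        if i == cfg.motif_spacer_index:
            motif = "G" + "A" * cfg.motif_run + "T"
            offset = (spacer_len - len(motif)) // 2
            spacer = spacer[:offset] + motif + spacer[offset + len(motif):]
            truth.motif = {
                "spacer_start": pos, "offset": offset,
                "genome_position": pos + offset, "run_length": cfg.motif_run,
            }
        truth.composition[f"spacer_{i}"] = _count(spacer)
        parts.append(spacer)
        pos += spacer_len
    genome = MitoGenome("ancestor", "".join(parts), circular=True, features=features)
    return genome, truth


def evolve_cds(
    seq: str, branch_length: float, omega: float,
    rng: np.random.Generator, code: GeneticCode,
    freeze_ends: bool = True,
) -> str:
    """Evolve one in-frame CDS under the proposal/acceptance scheme."""
    chars = list(seq)
    n = len(chars)
    n_events = rng.poisson(branch_length * n)
    ncod = n // 3
    for _ in range(n_events):
        p = int(rng.integers(0, n))
        ci = p // 3
        if freeze_ends and (ci == 0 or ci == ncod - 1):
            continue
        old = chars[p]
        alts = [b for b in _BASES if b != old]
        new = alts[int(rng.integers(0, 3))]
        codon = chars[3 * ci:3 * ci + 3]
        newcodon = codon.copy()
        newcodon[p % 3] = new
        c_old, c_new = "".join(codon), "".join(newcodon)
        if code.is_stop(c_new):
            continue
        if code.translate_codon(c_old) != code.translate_codon(c_new):
            if rng.random() >= omega:
                continue
        chars[p] = new
    return "".join(chars)


def _evolve_neutral(seq: str, branch_length: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    n = len(chars)
    for _ in range(rng.poisson(branch_length * n)):
        p = int(rng.integers(0, n))
        alts = [b for b in _BASES if b != chars[p]]
        chars[p] = alts[int(rng.integers(0, 3))]
    return "".join(chars)


def evolve_family(
    ancestor: MitoGenome, cfg: SimConfig, truth: SimTruth | None = None
) -> tuple[list[MitoGenome], SimTruth]:
    """Evolve one descendant per configured tip on a star tree.

    Substitution proposals arrive at ``branch_length x rate multiplier`` per
    site; CDS proposals are filtered through the stop/omega acceptance rule.
    Annotations carry over unchanged (no indels).
    """
    truth = truth or SimTruth(seed=cfg.seed, rate_multipliers=dict(cfg.rate_multipliers))
    rng = np.random.default_rng((cfg.seed, 1))
    code = GeneticCode.from_table_id(cfg.table_id)
    genomes: list[MitoGenome] = []
    n = len(ancestor)
    in_feature = np.zeros(n, dtype=bool)
    for f in ancestor.features:
        in_feature[np.arange(f.start, f.end) % n] = True
    for tip in cfg.tips:
        if tip.branch_length < 0 or tip.omega < 0:
            raise ValueError("branch length and omega must be >= 0")
        seq = list(ancestor.sequence)
        for f in ancestor.features:
            mult = cfg.rate_multipliers.get(f.name, 1.0)
            rate = tip.branch_length * mult
            sub = extract_feature_sequence(ancestor, f)
            if f.kind == "CDS":
                if f.strand != 1:
                    raise NotImplementedError("simulated CDS must lie on the + strand")
                evolved = evolve_cds(sub, rate, tip.omega, rng, code)
            else:
                evolved = _evolve_neutral(sub, rate, rng)
            for k, b in enumerate(evolved):
                seq[(f.start + k) % n] = b
        # intergenic positions evolve neutrally at the base rate
        spacer_positions = np.flatnonzero(~in_feature)
        if len(spacer_positions):
            spacer_seq = "".join(seq[p] for p in spacer_positions)
            evolved = _evolve_neutral(spacer_seq, tip.branch_length, rng)
            for p, b in zip(spacer_positions, evolved):
                seq[p] = b
        genomes.append(
            MitoGenome(tip.name, "".join(seq), circular=ancestor.circular,
                       features=list(ancestor.features), depth_class=tip.depth_class)
        )
        truth.tips.append({
            "name": tip.name, "branch_length": tip.branch_length,
            "omega": tip.omega, "depth_class": tip.depth_class,
        })
    return genomes, truth


def family_alignments(genomes: list[MitoGenome]) -> list[Alignment]:
    """Per-gene alignments of a simulated family (no indels, so extraction aligns)."""
    genes = [f.name for f in genomes[0].features]
    alns = []
    for gene in genes:
        seqs, ids = [], []
        for g in genomes:
            f = g.get_feature(gene)
            if f is None:
                raise ValueError(f"{g.id} lacks gene {gene}")
            seqs.append(extract_feature_sequence(g, f))
            ids.append(g.id)
        alns.append(Alignment(gene, ids, seqs))
    return alns


def concatenated_cds(genome: MitoGenome, drop_stops: bool = True) -> str:
    """13-PCG concatenation in annotation order, terminal stop codons removed."""
    parts = []
    for f in genome.features_of_kind("CDS"):
        seq = extract_feature_sequence(genome, f)
        if drop_stops and len(seq) % 3 == 0:
            seq = seq[:-3]
        parts.append(seq)
    return "".join(parts)


def emit(
    genomes: list[MitoGenome], truth: SimTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write FASTA + feature table per genome, per-gene alignments, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for g in genomes:
        fasta = out / f"{g.id}.fasta"
        table = out / f"{g.id}.features.tsv"
        write_fasta({g.id: g.sequence}, fasta)
        write_feature_table(g, table)
        written[f"{g.id}.fasta"] = fasta
        written[f"{g.id}.features"] = table
    if len(genomes) > 1:
        aln_dir = out / "alignments"
        aln_dir.mkdir(exist_ok=True)
        for aln in family_alignments(genomes):
            path = aln_dir / f"{aln.gene}.fasta"
            write_fasta(dict(zip(aln.ids, aln.seqs)), path)
            written[f"aln:{aln.gene}"] = path
    truth_path = out / "truth.json"
    truth_path.write_text(truth.to_json())
    written["truth"] = truth_path
    return written


__all__ = [
    "SimConfig", "SimTruth", "TipSpec",
    "DEFAULT_GENE_PLAN", "DEFAULT_SPACER_PLAN",
    "generate_ancestor", "evolve_family", "evolve_cds",
    "family_alignments", "concatenated_cds", "emit",
]
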