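"""Orchestration of the full comparative analysis behind one config object.

Stages run in a fixed order — summary, composition/skew, motif scan, codon
usage, gene order, nucleotide diversity, dN/dS contrast — and every table is
written as TSV plus a JSON mirror with deterministic row order, so a rerun
with the same config and inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .codon_usage import (
    GeneticCode,
    amino_acid_profile,
    audit_start_stop,
    compare_depth_groups,
    genome_codon_usage,
)
from .composition import count_bases, compute_skew, per_gene_skew_table, scan_genome_motifs, total_ign
from .diversity import Alignment, multi_gene_pi
from .gene_order import extract_gene_order, order_map, pairwise_breakpoints
from .mito_io import (
    MitoGenome,
    extract_feature_sequence,
    read_fasta,
    read_feature_table,
    read_genbank,
    write_report_tables,
)
from .selection import group_omega_contrast
from .simulate import concatenated_cds

log = logging.getLogger("mitocompare")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    genomes: list[dict] = field(default_factory=list)  # {"genbank": p} or {"fasta": p, "features": p}
    alignments_dir: str | None = None
    grouping: dict[str, str] = field(default_factory=dict)  # genome id -> deep|shallow
    table_id: int = 4
    window: int = 100
    step: int = 25
    min_run: int = 3
    out_dir: str = "mitocompare_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.window >= self.step >= 1):
            raise ValueError("need window >= step >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        grouping = data.get("grouping", {})
        if isinstance(grouping, str):  # a TSV path: id <tab> depth_class
            grouping = {
                parts[0]: parts[1]
                for line in Path(grouping).read_text().splitlines()
                if line.strip() and not line.startswith("#")
                for parts in [line.split("\t")]
            }
        data["grouping"] = grouping
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_genomes(cfg: PipelineConfig) -> list[MitoGenome]:
    genomes = []
    for entry in cfg.genomes:
        try:
            if "genbank" in entry:
                g = read_genbank(entry["genbank"])
            else:
                g = read_feature_table(entry["fasta"], entry["features"])
            g.depth_class = cfg.grouping.get(g.id, g.depth_class)
            genomes.append(g)
        except Exception as exc:  # continue past unreadable inputs
            log.error("could not read %s: %s", entry, exc)
    return genomes


def run_summary(genomes: list[MitoGenome]) -> pd.DataFrame:
    """Per-genome organization summary: lengths, gene counts, rRNA stats, IGN, skews."""
    columns = [
        "genome", "length", "depth_class", "n_cds", "n_trna", "n_rrna",
        "at_percent", "gc_percent", "at_skew", "gc_skew",
        "ign_total", "ign_regions", "ign_longest", "ign_longest_between",
        "s_rrna_len", "s_rrna_at_percent", "l_rrna_len", "l_rrna_at_percent",
    ]
    rows = []
    for g in genomes:
        comp = count_bases(g.sequence)
        skew = compute_skew(comp)
        ign_total, ign_count, longest = total_ign(g)
        row = {
            "genome": g.id, "length": len(g), "depth_class": g.depth_class,
            "n_cds": len(g.features_of_kind("CDS")),
            "n_trna": len(g.features_of_kind("tRNA")),
            "n_rrna": len(g.features_of_kind("rRNA")),
            "at_percent": comp.at_percent, "gc_percent": comp.gc_percent,
            "at_skew": skew.at_skew, "gc_skew": skew.gc_skew,
            "ign_total": ign_total, "ign_regions": ign_count,
            "ign_longest": longest.length if longest else 0,
            "ign_longest_between": (
                f"{longest.flanking_upstream}|{longest.flanking_downstream}" if longest else ""
            ),
        }
        for name in ("s-rRNA", "l-rRNA"):
            f = g.get_feature(name)
            key = name.replace("-", "_").lower()
            if f is None:
                row[f"{key}_len"] = 0
                row[f"{key}_at_percent"] = float("nan")
            else:
                c = count_bases(extract_feature_sequence(g, f))
                row[f"{key}_len"] = f.length
                row[f"{key}_at_percent"] = c.at_percent
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)


def load_alignments(aln_dir: str | Path) -> list[Alignment]:
    alns = []
    for path in sorted(Path(aln_dir).glob("*.fasta")):
        seqs = read_fasta(path)
        if len(seqs) >= 2:
            alns.append(Alignment(path.stem, list(seqs), list(seqs.values())))
    return alns


def run_all(cfg: PipelineConfig, genomes: list[MitoGenome] | None = None) -> Path:
    """Run every stage; tables land in ``cfg.out_dir``; returns the output dir.

    A failing stage raises :class:`StageError`; tables already written stay
    on disk.  Stages whose inputs are absent (no alignments, no grouping)
    are skipped with a warning.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if genomes is None:
        genomes = load_genomes(cfg)
    code = GeneticCode.from_table_id(cfg.table_id)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise StageError(name, exc) from exc

    summary = stage("summary", lambda: run_summary(genomes))
    write_report_tables(summary, out, "summary")
    if not genomes:
        log.warning("no readable genomes; header-only outputs")

    write_report_tables(stage("skew", lambda: per_gene_skew_table(genomes)), out, "skew")

    def motifs():
        rows = []
        for g in genomes:
            for h in scan_genome_motifs(g, cfg.min_run):
                rows.append({
                    "genome": g.id, "region_start": h.start, "run_length": h.run_length,
                    "flank_up": h.context_region.flanking_upstream if h.context_region else "",
                    "flank_down": h.context_region.flanking_downstream if h.context_region else "",
                })
        return pd.DataFrame(rows, columns=["genome", "region_start", "run_length",
                                           "flank_up", "flank_down"])
    write_report_tables(stage("motif", motifs), out, "motifs")

    def codon_stage():
        audits, rscu_rows, profiles = [], [], []
        for g in genomes:
            audits.append(audit_start_stop(g, code))
            table = genome_codon_usage(g, code)
            rscu_rows.append(table.to_frame().assign(genome=g.id))
            profiles.append(amino_acid_profile(table, g.id))
        audit_df = pd.concat(audits, ignore_index=True) if audits else pd.DataFrame()
        rscu_df = pd.concat(rscu_rows, ignore_index=True) if rscu_rows else pd.DataFrame()
        prof_df = pd.DataFrame([
            {"genome": p.genome_id,
             **{f"aa_{a}": v for a, v in sorted(p.aa_percent.items())},
             **{f"class_{c}": v for c, v in sorted(p.class_percent.items())}}
            for p in profiles
        ])
        return audit_df, rscu_df, prof_df, profiles

    audit_df, rscu_df, prof_df, profiles = stage("codon_usage", codon_stage)
    write_report_tables(audit_df, out, "start_stop_audit")
    write_report_tables(rscu_df, out, "rscu")
    write_report_tables(prof_df, out, "aa_profiles")

    if cfg.grouping and profiles:
        write_report_tables(
            stage("depth_groups", lambda: compare_depth_groups(profiles, cfg.grouping)),
            out, "aa_group_comparison",
        )

    def orders():
        ords = [extract_gene_order(g) for g in genomes]
        return pairwise_breakpoints(ords) if len(ords) > 1 else pd.DataFrame(), (
            order_map(ords) if ords else pd.DataFrame()
        )
    bp_df, map_df = stage("gene_order", orders)
    write_report_tables(bp_df, out, "breakpoints")
    write_report_tables(map_df, out, "gene_order_map")

    if cfg.alignments_dir and Path(cfg.alignments_dir).is_dir():
        def pi_stage():
            alns = load_alignments(cfg.alignments_dir)
            ranking, tracks = multi_gene_pi(alns, cfg.window, cfg.step)
            frames = [t.to_frame() for t in tracks if t.windows]
            windows = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
                columns=["gene", "window_start", "window_end", "midpoint", "pi"]
            )
            return ranking, windows
        ranking, windows = stage("diversity", pi_stage)
        write_report_tables(ranking, out, "pi_per_gene")
        write_report_tables(windows, out, "pi_windows")
    else:
        log.warning("no alignment directory; skipping diversity stage")

    groups = set(cfg.grouping.values())
    if {"deep", "shallow"} <= groups:
        def dnds():
            cds = {g.id: concatenated_cds(g) for g in genomes
                   if g.features_of_kind("CDS") and g.id in cfg.grouping}
            lengths = {len(s) for s in cds.values()}
            if len(lengths) != 1:
                raise ValueError("concatenated CDS lengths differ; inputs must be aligned")
            contrast, table = group_omega_contrast(cds, cfg.grouping)
            summary_row = pd.DataFrame([contrast.__dict__])
            return table, summary_row
        table, contrast_df = stage("selection", dnds)
        write_report_tables(table, out, "omega_pairs")
        write_report_tables(contrast_df, out, "omega_contrast")
    else:
        log.warning("no deep/shallow grouping; skipping selection stage")

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_genomes": len(genomes),
        "genome_ids": [g.id for g in genomes],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


__all__ = ["PipelineConfig", "StageError", "load_genomes", "load_alignments",
           "run_summary", "run_all"]
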