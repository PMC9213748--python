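"""Nei–Gojobori (1986) pairwise dN/dS with Jukes–Cantor correction.

Method summary: every codon position contributes fractional synonymous and
nonsynonymous *sites* according to the fate of its three possible single-base
changes (changes creating a stop codon are excluded from the possible set);
observed codon differences are split into synonymous and nonsynonymous
*differences* by averaging over all mutational pathways between the two
codons, excluding pathways that pass through a stop.  Proportions pS = Sd/S
and pN = Nd/N are corrected with the Jukes–Cantor formula
``d = -(3/4) ln(1 - (4/3) p)``, and omega = dN/dS.

This is a pairwise counting estimator, not a likelihood branch model; every
table it emits is labeled ``method: NG86-pairwise`` so the two are never
conflated.  The group contrast reports mean pairwise omega within the deep
(foreground) and shallow (background) groups and their background/foreground
fold ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from math import log

import pandas as pd

from .codon_usage import GeneticCode, split_codons

METHOD_LABEL = "NG86-pairwise"
_BASES = "ACGT"


@dataclass(frozen=True)
class NGCounts:
    S: float   # synonymous sites
    N: float   # nonsynonymous sites
    Sd: float  # synonymous differences (pathway-averaged)
    Nd: float  # nonsynonymous differences
    codons_compared: int


@dataclass(frozen=True)
class PairwiseOmega:
    id_a: str
    id_b: str
    counts: NGCounts
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float
    flag: str = ""  # "", "dS_zero", "jc_undefined", "identical"

    @property
    def defined(self) -> bool:
        return self.flag == ""


@dataclass(frozen=True)
class GroupOmegaContrast:
    foreground_omega: float
    background_omega: float
    fold_ratio: float  # background / foreground
    n_foreground_pairs: int
    n_background_pairs: int
    foreground_kind: str  # "deep-deep" or "deep-vs-shallow"
    method: str = METHOD_LABEL


@lru_cache(maxsize=None)
def _codon_site_counts(codon: str, table_id: int) -> tuple[float, float]:
    """(synonymous sites, nonsynonymous sites) for one sense codon."""
    code = GeneticCode.from_table_id(table_id)
    aa = code.translate_codon(codon)
    s = n = 0.0
    for pos in range(3):
        syn = possible = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if code.is_stop(alt):
                continue
            possible += 1
            if code.translate_codon(alt) == aa:
                syn += 1
        if possible == 0:  # cannot happen for sense codons in table 4, kept for safety
            n += 1.0
            continue
        s += syn / possible
        n += 1.0 - syn / possible
    return s, n


def ng_site_counts(cds: str, code: GeneticCode) -> tuple[float, float]:
    """Total (S, N) site counts over a stop-free codon sequence.

    Raises on internal stop codons, naming the codon index; a single terminal
    stop codon is tolerated and excluded from the counts.
    """
    codons = split_codons(cds)
    if codons and code.is_stop(codons[-1]):
        codons = codons[:-1]
    S = N = 0.0
    for i, codon in enumerate(codons):
        if "N" in codon:
            continue
        if code.is_stop(codon):
            raise ValueError(f"internal stop codon at codon index {i}")
        s, n = _codon_site_counts(codon, code.table_id)
        S += s
        N += n
    return S, N


@lru_cache(maxsize=None)
def _codon_diff_counts(c1: str, c2: str, table_id: int) -> tuple[float, float, bool]:
    """Pathway-averaged (Sd, Nd) between two sense codons.

    Returns (Sd, Nd, used_fallback); the fallback classifies each differing
    position independently when every ordering of the changes passes through
    a stop codon.
    """
    code = GeneticCode.from_table_id(table_id)
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0, False
    outcomes = []
    for path in permutations(positions):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in path:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if code.is_stop(nxt):
                ok = False
                break
            if code.translate_codon(nxt) == code.translate_codon(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            outcomes.append((sd, nd))
    if outcomes:
        sd = sum(o[0] for o in outcomes) / len(outcomes)
        nd = sum(o[1] for o in outcomes) / len(outcomes)
        return sd, nd, False
    # all pathways blocked by stops: per-position direct classification
    sd = nd = 0.0
    for pos in positions:
        alt = c1[:pos] + c2[pos] + c1[pos + 1:]
        if code.is_stop(alt) or code.translate_codon(alt) != code.translate_codon(c1):
            nd += 1
        else:
            sd += 1
    return sd, nd, True


def ng_difference_counts(a: str, b: str, code: GeneticCode) -> tuple[float, float]:
    """(Sd, Nd) summed over aligned codons; codons containing N are skipped."""
    ca, cb = split_codons(a), split_codons(b)
    if len(ca) != len(cb):
        raise ValueError("sequences differ in codon count")
    if ca and code.is_stop(ca[-1]) and code.is_stop(cb[-1]):
        ca, cb = ca[:-1], cb[:-1]
    Sd = Nd = 0.0
    for i, (x, y) in enumerate(zip(ca, cb)):
        if "N" in x or "N" in y:
            continue
        if code.is_stop(x) or code.is_stop(y):
            raise ValueError(f"internal stop codon at codon index {i}")
        sd, nd, fallback = _codon_diff_counts(x, y, code.table_id)
        if fallback:
            warnings.warn(f"codon {i}: all pathways pass through stops; split per position")
        Sd += sd
        Nd += nd
    return Sd, Nd


def jukes_cantor(p: float) -> float:
    """JC69 distance; NaN when p >= 3/4 (correction undefined)."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def pairwise_omega(
    a: str, b: str, code: GeneticCode | None = None,
    id_a: str = "a", id_b: str = "b",
) -> PairwiseOmega:
    """NG86 omega for one aligned codon-sequence pair.

    Site counts are averaged over the two sequences.  omega is flagged
    undefined when dS = 0 (including identical sequences) or when either
    Jukes–Cantor correction is undefined.
    """
    code = code or GeneticCode.from_table_id(4)
    Sa, Na = ng_site_counts(a, code)
    Sb, Nb = ng_site_counts(b, code)
    S, N = (Sa + Sb) / 2.0, (Na + Nb) / 2.0
    Sd, Nd = ng_difference_counts(a, b, code)
    ncod = min(len(a), len(b)) // 3
    counts = NGCounts(S, N, Sd, Nd, ncod)
    pS = Sd / S if S > 0 else float("nan")
    pN = Nd / N if N > 0 else float("nan")
    dS, dN = jukes_cantor(pS) if pS == pS else float("nan"), \
        jukes_cantor(pN) if pN == pN else float("nan")
    flag = ""
    if Sd == 0 and Nd == 0:
        flag = "identical"
        omega = float("nan")
    elif dS != dS or dN != dN:
        flag = "jc_undefined"
        omega = float("nan")
    elif dS == 0:
        flag = "dS_zero"
        omega = float("nan")
    else:
        omega = dN / dS
    return PairwiseOmega(id_a, id_b, counts, pS, pN, dS, dN, omega, flag)


def omega_table(pairs: list[PairwiseOmega]) -> pd.DataFrame:
    rows = [
        {
            "id_a": p.id_a, "id_b": p.id_b,
            "S": p.counts.S, "N": p.counts.N, "Sd": p.counts.Sd, "Nd": p.counts.Nd,
            "pS": p.pS, "pN": p.pN, "dS": p.dS, "dN": p.dN,
            "omega": p.omega, "flag": p.flag, "method": METHOD_LABEL,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows)


def group_omega_contrast(
    cds_by_genome: dict[str, str],
    grouping: dict[str, str],
    code: GeneticCode | None = None,
) -> tuple[GroupOmegaContrast, pd.DataFrame]:
    """Deep (foreground) vs shallow (background) mean pairwise omega.

    ``cds_by_genome`` maps genome id to its concatenated, codon-aligned CDS
    sequence.  With at least two deep genomes the foreground mean is over
    deep–deep pairs; with exactly one it falls back to deep-vs-shallow pairs
    and is labeled as such.  Pairs with undefined omega are dropped with a
    warning.
    """
    code = code or GeneticCode.from_table_id(4)
    deep = sorted(g for g, grp in grouping.items() if grp == "deep" and g in cds_by_genome)
    shallow = sorted(g for g, grp in grouping.items() if grp == "shallow" and g in cds_by_genome)
    if not deep or len(shallow) < 2:
        raise ValueError("need >= 1 deep and >= 2 shallow genomes")

    def mean_omega(pairs: list[tuple[str, str]]) -> tuple[float, int, list[PairwiseOmega]]:
        results = [
            pairwise_omega(cds_by_genome[x], cds_by_genome[y], code, x, y) for x, y in pairs
        ]
        ok = [r.omega for r in results if r.defined]
        dropped = len(results) - len(ok)
        if dropped:
            warnings.warn(f"{dropped} pair(s) with undefined omega dropped")
        return (sum(ok) / len(ok) if ok else float("nan")), len(ok), results

    if len(deep) >= 2:
        fg_pairs = list(combinations(deep, 2))
        fg_kind = "deep-deep"
    else:
        fg_pairs = [(deep[0], s) for s in shallow]
        fg_kind = "deep-vs-shallow"
    bg_pairs = list(combinations(shallow, 2))
    fg, n_fg, res_fg = mean_omega(fg_pairs)
    bg, n_bg, res_bg = mean_omega(bg_pairs)
    fold = bg / fg if fg == fg and bg == bg and fg > 0 else float("nan")
    contrast = GroupOmegaContrast(fg, bg, fold, n_fg, n_bg, fg_kind)
    return contrast, omega_table(res_fg + res_bg)


__all__ = [
    "NGCounts", "PairwiseOmega", "GroupOmegaContrast", "METHOD_LABEL",
    "ng_site_counts", "ng_difference_counts", "jukes_cantor",
    "pairwise_omega", "omega_table", "group_omega_contrast",
]
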