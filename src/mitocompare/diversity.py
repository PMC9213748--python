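"""Nucleotide diversity (Pi) per gene and in sliding windows.

Pi is the average proportion of differing sites over all sequence pairs.
The default site filter is complete deletion: any column containing a gap
or N in any sequence is dropped from numerator and denominator, matching
the DnaSP convention; a pairwise-deletion mode is available behind a flag.
No multiple-hit correction is applied (raw Pi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .mito_io import CANONICAL_GENE_ORDER

_GOOD = frozenset(b"ACGT")


@dataclass
class Alignment:
    gene: str
    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.seqs) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene}: unequal row lengths {sorted(lengths)}")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n_seqs(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def matrix(self) -> np.ndarray:
        return np.frombuffer("".join(self.seqs).encode(), dtype=np.uint8).reshape(
            self.n_seqs, self.length
        )


@dataclass
class PiTrack:
    gene: str
    pi: float
    n_sites: int
    n_seqs: int
    window: int
    step: int
    windows: list[tuple[int, int, float, float]] = field(default_factory=list)
    # (start, end, midpoint, pi); pi is NaN for windows with no analyzable sites

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.windows, columns=["window_start", "window_end", "midpoint", "pi"]
        ).assign(gene=self.gene)[["gene", "window_start", "window_end", "midpoint", "pi"]]


def _good_mask(mat: np.ndarray) -> np.ndarray:
    ok = np.zeros(mat.shape, dtype=bool)
    for b in _GOOD:
        ok |= mat == b
    return ok


def pairwise_pi(
    aln: Alignment,
    site_mask: np.ndarray | None = None,
    pairwise_deletion: bool = False,
) -> tuple[float, int]:
    """(Pi, number of analyzed sites).

    Complete deletion (default): columns with any gap/N excluded globally.
    Pairwise deletion: each pair compared over its own clean columns; the
    returned site count is then the number of columns clean in >= 2 rows.
    ``site_mask`` (boolean over columns) restricts the analysis, e.g. to a
    window.  Pi is NaN when no analyzable site remains.
    """
    mat = aln.matrix()
    if site_mask is not None:
        mat = mat[:, site_mask]
    ok = _good_mask(mat)
    if pairwise_deletion:
        diffs, sites = [], []
        for i, j in combinations(range(aln.n_seqs), 2):
            both = ok[i] & ok[j]
            n = int(both.sum())
            if n:
                diffs.append(int((mat[i, both] != mat[j, both]).sum()) / n)
        n_sites = int((ok.sum(axis=0) >= 2).sum())
        if not diffs:
            return float("nan"), n_sites
        return float(np.mean(diffs)), n_sites
    clean = ok.all(axis=0)
    n_sites = int(clean.sum())
    if n_sites == 0:
        return float("nan"), 0
    sub = mat[:, clean]
    npairs = aln.n_seqs * (aln.n_seqs - 1) // 2
    # per-column pairwise differences from base counts: npairs - sum_b C(k_b, 2)
    same = np.zeros(n_sites)
    for b in _GOOD:
        k = (sub == b).sum(axis=0)
        same += k * (k - 1) / 2
    total_diffs = npairs * n_sites - same.sum()
    return float(total_diffs / npairs / n_sites), n_sites


def sliding_window_pi(
    aln: Alignment, window: int = 100, step: int = 25,
    pairwise_deletion: bool = False,
) -> PiTrack:
    """Whole-alignment Pi plus Pi in windows [k*step, k*step + window).

    Trailing partial windows are dropped; an alignment shorter than one
    window yields the per-gene value with an empty window list.
    """
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    pi, n_sites = pairwise_pi(aln, pairwise_deletion=pairwise_deletion)
    track = PiTrack(aln.gene, pi, n_sites, aln.n_seqs, window, step)
    if aln.length < window:
        warnings.warn(f"{aln.gene}: alignment ({aln.length} bp) shorter than window")
        return track
    for start in range(0, aln.length - window + 1, step):
        mask = np.zeros(aln.length, dtype=bool)
        mask[start:start + window] = True
        wpi, _ = pairwise_pi(aln, site_mask=mask, pairwise_deletion=pairwise_deletion)
        track.windows.append((start, start + window, start + window / 2, wpi))
    return track


def multi_gene_pi(
    alignments: list[Alignment], window: int = 100, step: int = 25,
) -> tuple[pd.DataFrame, list[PiTrack]]:
    """Per-gene Pi ranking plus per-gene window tracks.

    The ranking is sorted by Pi descending; ties fall back to canonical gene
    order so the output is deterministic.
    """
    tracks = [sliding_window_pi(a, window, step) for a in alignments]
    order = {g: i for i, g in enumerate(CANONICAL_GENE_ORDER)}
    ranked = sorted(
        tracks, key=lambda t: (-(t.pi if t.pi == t.pi else -1.0), order.get(t.gene, 99), t.gene)
    )
    table = pd.DataFrame(
        [
            {"gene": t.gene, "pi_total": t.pi, "n_sites": t.n_sites, "n_seqs": t.n_seqs,
             "rank": i + 1}
            for i, t in enumerate(ranked)
        ]
    )
    return table, tracks


__all__ = ["Alignment", "PiTrack", "pairwise_pi", "sliding_window_pi", "multi_gene_pi"]
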