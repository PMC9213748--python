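# Methods

`mitocompare` implements the comparative statistics commonly applied to
animal mitochondrial genomes — here tuned to sea-anemone (Actiniaria)
mitogenomes, which are circular ~16–20 kb molecules carrying 13 energy-pathway
protein-coding genes (PCGs), two rRNAs and only two tRNAs, typically all on
the heavy strand. This note records the definitions, conventions and design
choices each module uses, and what the simulator does and does not emulate.

## Coordinates and I/O

Internal coordinates are 0-based half-open; all file formats (GenBank, the
TSV feature table) use the 1-based inclusive GenBank dialect. A feature may
wrap the origin of a circular molecule; internally this is represented by
`end > genome length` with modular arithmetic, which keeps span lengths and
extraction trivial to reason about. Minus-strand features are measured on
the coding (extracted, reverse-complemented) strand everywhere in the
package. Gene labels are normalized through an editable synonym table
(`data/gene_synonyms.tsv`); unknown labels pass through verbatim. Ambiguity
codes other than N are rejected at parse time: every downstream statistic is
defined on the four bases, and silently interpreting IUPAC codes would bias
counts. N is accepted, tracked, and excluded from every denominator.

## Composition and skew

AT skew = (A − T)/(A + T), GC skew = (G − C)/(G + C). A zero denominator
gives a flagged undefined value, never an exception or a clamped number.
The "PCGs" aggregate scope is the concatenation of the 13 canonical PCGs in
canonical label order, stop codons included; the "rRNAs" scope concatenates
the two rRNAs. Intergenic nucleotides (IGN) are the positions covered by no
annotated feature, reported as maximal runs on the circle with their
flanking genes; overlapping annotations are tolerated with a warning since
anemone mitogenomes are expected to be overlap-free. The control-region-like
motif scan finds all maximal G·A^k·T matches with k at least `min_run`
(default 3; the published descriptions write the run length as "(A)n"
without fixing n, so it is configurable). On circular input the scan crosses
the origin.

## Codon usage

The genetic code defaults to NCBI translation table 4 (mold / protozoan /
coelenterate mitochondrial: stops TAA and TAG, TGA = Trp), taken from
Biopython's table rather than retyped. Stop codons are tallied separately
and excluded from usage counts, amino-acid percentages and RSCU — both the
sense-only and the stops-included codon totals are reported, because the two
conventions differ by exactly one codon per gene and published totals do not
always say which was used. RSCU is count over synonymous-family mean; a
family with zero total stays undefined (NaN), not zero. Residue classes are
nonpolar {G,A,V,L,I,P,F,M,W}, polar uncharged {S,T,C,Y,N,Q} and charged
{D,E,K,R,H}; this partition is a documented choice among the several in
circulation. The depth-group comparison runs a two-sided Welch t-test per
amino acid and per class; no multiple-testing correction is applied to the
primary p-value (a Bonferroni column is emitted alongside), and any group
with fewer than three members carries a `small_group` or
`untestable_group_size` flag — hadal datasets genuinely have n = 2 deep
genomes, so the flag matters.

## Nucleotide diversity

Pi is the mean proportion of differing sites over all sequence pairs of an
alignment. The default site filter is complete deletion (columns containing
a gap or N in any sequence are excluded globally), matching DnaSP's default;
pairwise deletion is available behind a flag. No Jukes–Cantor correction is
applied to Pi (raw Pi, again the DnaSP convention). Sliding windows are
`[k·step, k·step + window)` on alignment coordinates with defaults 100/25 bp;
trailing partial windows are dropped and midpoints reported for plotting.
Per-gene ranking breaks ties by canonical gene order so output is
deterministic.

## Gene order

Orders are signed circular sequences of gene labels (tRNAs included),
compared through their directed signed adjacency sets, which are invariant
under rotation. Reflection is deliberately not normalized away: strand is
biologically meaningful in these genomes, and a whole-molecule flip is a
real difference. The breakpoint distance between two orders restricted to
their shared gene set is the number of adjacencies of one absent from the
other; on equal gene sets it is symmetric, and zero exactly when the orders
are identical up to rotation.

## NG86 dN/dS

The selection module is a Nei–Gojobori (1986) pairwise counting estimator:
per-codon synonymous/nonsynonymous site fractions with stop-creating changes
excluded from the possible-change set; observed differences split by
averaging over all mutational pathways between codon pairs, pathways through
stops excluded and remaining pathways equally weighted; when every pathway
is blocked the differences are classified per position directly, with a
warning. Proportions are corrected with Jukes–Cantor
(d = −(3/4)·ln(1 − 4p/3)); p ≥ 3/4 yields a flagged undefined distance,
never a clamped number. omega = dN/dS is undefined when dS = 0.

The deep-vs-shallow contrast reports the mean pairwise omega among deep
(foreground) genomes and among shallow (background) genomes, and their
background/foreground fold ratio. With a single deep genome the foreground
falls back to deep-vs-shallow pairs and is labeled as such. This is a
deliberate, auditable stand-in for likelihood branch models (CodeML M0 /
free-ratio / two-ratio): every output table carries `method: NG86-pairwise`
so the two are never conflated, and no likelihood machinery is implemented.

## Simulator

The generator's default plan is the canonical 17-gene actiniarian layout
with realistic gene lengths (PCG total 12,105 bp; rRNAs 1,055 and 2,162 bp;
two 71 bp tRNAs), 17 intergenic spacers totalling 1,112 bp with the longest
(223 bp) between ND5 and ND1 and a 147 bp spacer between s-rRNA and cox2
carrying an embedded G(A)5T motif; composition targets default to
A+T 62.4%, AT skew −0.12, GC skew +0.121. These defaults are the study
conditions the analysis stages are validated against, not tuning knobs.

Bases (and, within CDSs, whole codons drawn from a stop-free weight table
derived from the per-base targets) are laid down by largest-remainder quota
sampling and then shuffled, so realized composition hits the targets to
within rounding (~±0.005 on a skew at 16 kb) and the seed controls only the
arrangement; iid sampling would leave ~0.012 sd on the whole-genome GC skew
and make closure checks at ±0.02 unreliable. Excluding stop codons from the
CDS weight table shifts realized A+T down by roughly one percentage point
relative to the naive target; the realized values, not the targets, are what
truth-closure tests compare against. Every CDS starts ATG and ends TAA
(ND3: TAG), matching the observed convention.

Families evolve on a star tree. Each branch receives Poisson substitution
proposals at `branch_length × per-gene rate multiplier` per site, uniform
over the three alternative bases. Within a CDS a proposal creating a stop is
rejected and a nonsynonymous proposal is accepted with probability
`omega_true` (synonymous proposals always accepted); start and stop codons
are frozen so the start/stop audit is invariant across a family. This
acceptance-thinning scheme imposes omega without codon-matrix
exponentiation and is what the NG86 recovery tests close the loop on. There
is no indel process — no analysis stage here needs gaps, and their absence
keeps per-gene alignments exact — and no rate heterogeneity within a gene,
no secondary-structure-aware rRNA evolution, no strand asymmetry in the
mutation process. Passing recovery tests therefore demonstrates estimator
correctness under the model's own assumptions, not robustness to alignment
error, saturation or compositional drift in real data.

## Problem sizes and numerical conventions

Recovery checks use 10 seeds for composition closure and Pi ranking
(6 tips, branch length 0.06, multipliers atp8 3.0 / l-rRNA 0.25), 10
replicate 3,000-codon pairs per omega in {0.05, 0.2, 1.0} at branch length
0.05, and a 3 deep / 6 shallow family of 3,000-codon sequences at branch
length 0.12 with omega 0.05 vs 0.12 for the fold-ratio contrast — sizes at
which Poisson counting noise puts the mean estimates comfortably inside the
stated recovery bands (±20% on omega, ±30% on the 2.4-fold ratio). Report
tables print floats at 4 decimals; undefined values propagate as NaN with an
explanatory flag column rather than sentinel numbers. Pipeline reruns with
identical config, inputs and seed are byte-identical.
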