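# Methods

## Analysis unit and coordinate conventions

The analysis unit is the homoeologous tetrad: one gene in each of the two
diploid genomes (Ar, Co) and the two allotetraploid subgenomes (An, Cn),
with strict 1:1:1:1 correspondence.  All internal coordinates are 0-based
half-open; GFF3 (1-based inclusive) is converted at the file boundary, BED is
used natively.  Promoters are 1.5 kb upstream plus 0.5 kb downstream of the
TSS, read 5′→3′ in transcription direction; on the minus strand the genomic
window is `[tss − 500, tss + 1500)` and the sequence is reverse-complemented.
Clipping at chromosome ends is allowed and flagged.

## Tetrad identification

Orthology uses reciprocal best hits over the promoter-anchored gene
sequences.  Candidate partners are nominated by shared unique 13-mers
(vectorised sorted-array join; for each gene the top 3 partners, discarding
partners with less than half the best shared count), then scored by banded
global alignment (match +1, mismatch −1, gap −2, band half-width 448 plus
the length difference).  A pair is kept iff mutually best; ties break
lexicographically and are flagged ambiguous.  The cscore of a pair is its
score divided by the best score of either gene (MCScan's convention);
pairs must reach cscore ≥ 0.99 and belong to a collinear chain of ≥ 4
anchors, monotone in both genomes (either orientation) with ≤ 10 gene-rank
gaps, found by longest-chain dynamic programming (forward + backward pass,
so the reported chain length is the longest chain *through* each pair).
Quartets are assembled from the Ar–Co, Ar–An and Co–Cn maps; the An–Cn edge
must agree when present and can be required (`require_closed_quartet`).  Any
gene in more than one candidate quartet discards all its quartets.  The
enforcement order (synteny filter, then 1:1:1:1) is the default; both orders
are defensible and only this one is implemented in the pipeline path.

The band half-width is deliberately generous: simulated promoters can
accumulate several hundred bases of deletions (footprint losses, background
structural deletions), and the true alignment path must stay inside the band
for the similarity score to rank partners correctly.

## Promoter alignment and lift-over

Homoeologous promoter pairs are aligned with one global affine-gap
alignment: match +2, mismatch −3, gap open −5, gap extend −2 (a gap of
length L costs open + (L−1)·extend).  N never matches.  Traceback is fully
deterministic — ties prefer diagonal, then gap-in-A, then gap-in-B, and gap
extension over re-opening — so aligned columns are a pure function of the
inputs.  The kernel is a numba-jitted Gotoh DP with rolling score rows and a
packed one-byte-per-cell pointer matrix; the test suite proves score
equality against a full-matrix reference DP.

An interval lifts through the alignment as the `[min, max)` hull of the
partner positions of its aligned bases.  `lifted_fraction` is the fraction
of source bases with an aligned partner base; a lift succeeds when it
reaches `min_lift` (default 0.5, the common lift-over default).
`identity_in_region` counts the source bases in match columns over the
interval width, so gaps count against identity.

## Conservation classes

Per tetrad, pair and mark, with peaks first intersected with the promoters
(promoter coordinates):

* sequence conserved ⇔ **every** promoter peak of the mark, in whichever
  member has peaks, lifts successfully with identity ≥ 0.7 in its footprint;
* epigenome conserved ⇔ **some** lifted peak region is covered ≥ 0.5 by a
  same-mark partner peak (either direction suffices).

The ALL/ANY choices are switchable; the defaults are conservative for
sequence (one disrupted peak breaks conservation) and robust for epigenome
(peak-boundary noise should not break it).  Class I/II/III follow the two
booleans; the logically possible fourth state (epigenome conserved on a
divergent sequence) is reported `unclassified` and excluded from class
denominators rather than forced into Class III, which would distort
proportions.  Pairs with no peak on either side are `no_peak`.  H3K9me2 is
processed like every mark but excluded from class summary tables by default.

## Convergence

For each mark, tetrads whose An–Cn feature is conserved are categorised by
their Ar–Co status: `same` (conserved there too), `convergent` (Ar–Co has
peaks but is not conserved), `others` (no Ar–Co peak).  The epigenomic layer
conditions on epigenome conservation, the sequence layer on sequence
conservation (Class I or II).  `others` means strictly "no peak";
`unclassified` Ar–Co calls categorise by their conservation booleans.
Expression convergence is |log2FC(An,Cn)| < 1 ≤ |log2FC(Ar,Co)| with
log2FC = log2((max TPM + 1)/(min TPM + 1)); both the threshold and the
pseudocount are configurable, and the threshold matches the package's DEG
filter (p < 0.05 and |log2FC| > 1, both strict).

## Statistics

2×2 contingency tables use Pearson's chi-square with Yates continuity
correction by default (scipy backend, proven equal to the closed-form 2×2
formula by a property test); p-values below 2.2e−16 are reported as
"<2.2e−16".  Marked-gene shifts are (tetraploid − diploid) / tetrad-total ×
100.  TPM differences are binned into [0,1), [1,5), [5,10), [10,∞).
Distribution comparisons use two-sided Mann–Whitney U.  Signal–expression
coupling is Pearson r on log2(TPM + 1).

## TFBS scanning and conservation

Motifs are JASPAR-style count matrices, normalised with pseudocount 1e−3.
A window scores Σ ln(p/0.25) (natural-log odds, uniform background); both
strands are scanned, every hit with score > 10 is kept, overlapping hits
included, and windows containing N are skipped (their score is −∞).  The
batched scanner is proven equal to a brute-force all-window scorer.  A
tetraploid promoter hit is conserved when its motif is identified in the
diploid homoeolog (presence/absence at motif identity, not position — the
natural reading of "identified in both homologs"); CS = conserved hits /
total hits on a 0–1 scale, undefined for promoters without hits, and the
high-conservation fraction uses CS > 0.6 strictly.

## Variants

Variants are read off the aligned promoter columns: each mismatch column is
one SNV (no MNV merging); each maximal gap run in one sequence is one InDel
(≤ 50 bp) or SV (> 50 bp); a run interrupted by an aligned column splits.
Positions are reported on the tetraploid member; records keep enough ref/alt
context that editing the diploid sequence with the variant list reconstructs
the tetraploid sequence exactly (tested on a thousand simulated pairs).
A variant overlaps a nonconserved TFBS when its footprint intersects a
nonconserved hit window by ≥ 1 bp (half-open).  Gap length is measured as
the alignment gap-run length, whichever strand carries the bases.

## Synthetic benchmark

The generator derives four genomes from one ancestral gene set along a
two-lineage tree: ancestor → A-lineage midpoint → {Ar, An} and ancestor →
C-lineage midpoint → {Co, Cn}.  The extant diploid is a *sibling* of the
subgenome, not its parent — essential, because a parent/child structure
would make every subgenome TFBS trivially present in the diploid and erase
conservation-score variation.  The A lineage's sibling branches run at 1.5×
the background rates, making the Ar–An comparison carry more variants and An
the less conserved subgenome.  Per gene and lineage, all rates are further
multiplied by a lognormal heterogeneity factor (σ = 0.6, capped at 4×):
mutationally hot promoters accumulate both more variant length and more
TFBS turnover, which is what couples variant burden to conservation scores.
Defaults: 2000 tetrads on 2 chromosomes, 2 kb promoters with i.i.d. uniform
sequence, 50% minus-strand genes, per-branch SNV rate 0.02, small-indel rate
0.001 (1–10 bp), a 5% per-promoter chance of a 60–150 bp background
deletion, motif instances implanted from the packaged synthetic PWM library
(per-motif probability 0.25, consensus with 10% per-position noise), and a
0.25 per-instance, per-leaf-branch TFBS-turnover probability (disruption by
a small core deletion or dense substitution, only outside peak footprints).

Per mark (ancestral peak probability 0.7, footprints 120–250 bp in disjoint
slots ≥ 450 bp from the far upstream edge), the diploid→tetraploid pair
class is drawn from the class mix (default 55/25/20):

* Class I — peak kept in the derived member, footprint shielded from edits;
* Class II — peak lost, footprint still shielded;
* Class III — peak lost and footprint destroyed: either deleted outright
  (an SV) or densely substituted (40%) with one 10–30 bp deletion.

Convergence implants (15% epigenomic, 10% sequence, among marks with an
ancestral peak, mutually exclusive) force the An–Cn pair to be conserved
while Ar–Co diverges: the epigenomic mode removes only Co's peak; the
sequence mode densely diverges the footprint on the Ar branch and copies the
resulting An footprint sequence into Cn.  Length-changing destructive edits
are deletions, and footprints sit upstream-heavy in the window, so truth
footprints cannot drift out of the 2 kb extraction window; the TSS is
tracked exactly through every edit.

Expression is lognormal around a shared tetrad baseline (log2 mean 4,
σ 1.2): activating marks (H3K4me3, ACR) multiply expectation by
`mark_effect` = 2, H3K4me1 by √2, repressive marks divide by 2; per-member
log-noise grows with the pair's worst class (σ = 0.25/0.5/1.0 for I/II/III,
0.3 baseline).  This couples class labels to expression divergence and peak
presence to expression level, which is what the divergence and correlation
stages measure.

What the generator does **not** emulate: read-level noise and peak-calling
artefacts, transposable-element landscapes, methylation, genuine
evolutionary sequence composition, chromosomal rearrangements, and
biological correlation structure between marks.  Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
assumptions, not performance on real genomes.

## Problem sizes and determinism

The reference scenario is 2000 tetrads (seed 42); unit tests use 60, the
round-trip check 250 (= 1000 promoter pairs), the zero-noise invariant 100.
All randomness flows from one run seed through stage-keyed substreams, so
datasets and every result table are byte-identical across reruns; the run
manifest records per-table SHA-256 checksums.  A single worker is assumed;
the CLI's `--threads` flag is accepted for interface stability and never
changes results.

## Known limitations

* RBH-based orthology with synteny chaining is a desk-scale stand-in for
  proteome clustering plus genome-wide synteny; it assumes largely collinear
  genomes and will not resolve tandem duplications.
* The `unclassified` state and the ALL/ANY conservation semantics are this
  package's explicit choices where the three-class scheme is silent; both
  are configurable.
* TFBS conservation at motif-identity level ignores binding-site position;
  a position-matched mode would be stricter.
* With zero tetraploid hits CS is undefined and the gene is excluded from CS
  distributions, which slightly biases them toward motif-rich promoters.
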