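"""Promoter extraction, homoeologous promoter alignment and interval lift-over.

The promoter window is 1.5 kb upstream of the TSS plus 0.5 kb downstream
(2 kb total), taken in transcription direction: on the '-' strand the genomic
window is ``[tss - 500, tss + 1500)`` and the sequence is reverse-complemented
so every promoter reads 5'->3'.

Homoeologous promoter pairs are aligned with one global affine-gap alignment
(match +2, mismatch -3, gap open -5, gap extend -2, deterministic traceback)
and intervals are projected through the aligned columns.  A lift succeeds
when at least ``min_lift`` (default 0.5) of the source bases have an aligned
partner base; the target interval is the [min, max) hull of those partner
positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._aligner import encode, global_affine_align
from .io_formats import GeneModel, GenomeAssembly, log

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500
DEFAULT_MIN_LIFT = 0.5

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterRegion:
    """A strand-aware promoter window around a TSS.

    ``interval`` is the genomic 0-based half-open window; ``sequence`` reads
    5'->3' in transcription direction (reverse-complemented on '-').
    ``clipped`` is set when the window hit a chromosome end.
    """

    gene_id: str
    chrom: str
    strand: str
    interval: tuple[int, int]
    sequence: str
    clipped: bool = False

    def __len__(self) -> int:
        return self.interval[1] - self.interval[0]

    def to_promoter_coords(self, start: int, end: int) -> tuple[int, int]:
        """Map a genomic interval (already inside the window) to promoter
        offsets in transcription direction."""
        s0, e0 = self.interval
        if self.strand == "+":
            return (start - s0, end - s0)
        return (e0 - end, e0 - start)

    def to_genome_coords(self, start: int, end: int) -> tuple[int, int]:
        s0, e0 = self.interval
        if self.strand == "+":
            return (s0 + start, s0 + end)
        return (e0 - end, e0 - start)


@dataclass
class PromoterAlignment:
    """Global alignment of a homoeologous promoter pair.

    ``a_pos``/``b_pos`` give, per alignment column, the 0-based position in
    each sequence or -1 for a gap; ``match`` flags identical non-N columns.
    ``identity`` counts match columns over all columns (gap columns count
    against identity); coverages are the aligned fraction of each sequence.
    """

    gene_a: str
    gene_b: str
    seq_a: str
    seq_b: str
    a_pos: np.ndarray
    b_pos: np.ndarray
    match: np.ndarray
    score: float

    @property
    def n_columns(self) -> int:
        return len(self.a_pos)

    @property
    def identity(self) -> float:
        return float(self.match.sum()) / self.n_columns

    @property
    def coverage_a(self) -> float:
        both = (self.a_pos >= 0) & (self.b_pos >= 0)
        return float(both.sum()) / len(self.seq_a)

    @property
    def coverage_b(self) -> float:
        both = (self.a_pos >= 0) & (self.b_pos >= 0)
        return float(both.sum()) / len(self.seq_b)

    def swapped(self) -> "PromoterAlignment":
        """The same alignment viewed with the members exchanged."""
        return PromoterAlignment(
            gene_a=self.gene_b, gene_b=self.gene_a,
            seq_a=self.seq_b, seq_b=self.seq_a,
            a_pos=self.b_pos, b_pos=self.a_pos,
            match=self.match, score=self.score)


@dataclass
class LiftResult:
    """Projection of one interval through a promoter alignment."""

    source: tuple[int, int]
    target: tuple[int, int] | None
    lifted_fraction: float
    identity_in_region: float


def extract_promoter(gene: GeneModel, assembly: GenomeAssembly,
                     upstream: int = PROMOTER_UPSTREAM,
                     downstream: int = PROMOTER_DOWNSTREAM) -> PromoterRegion:
    """Extract the strand-aware promoter window for a gene, clipping at
    chromosome ends (a clipped window is flagged and logged)."""
    chrom_seq = assembly.sequences.get(gene.chrom)
    if chrom_seq is None:
        raise KeyError(f"gene {gene.gene_id!r}: chromosome {gene.chrom!r} "
                       f"not in assembly {assembly.label!r}")
    clen = len(chrom_seq)
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    cstart, cend = max(0, start), min(clen, end)
    clipped = (cstart, cend) != (start, end)
    if clipped:
        log.warning("promoter of %s clipped to [%d,%d) at chromosome bounds",
                    gene.gene_id, cstart, cend)
    seq = chrom_seq[cstart:cend]
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return PromoterRegion(gene_id=gene.gene_id, chrom=gene.chrom,
                          strand=gene.strand, interval=(cstart, cend),
                          sequence=seq, clipped=clipped)


def align_promoters(seq_a: str, seq_b: str,
                    gene_a: str = "A", gene_b: str = "B") -> PromoterAlignment:
    """Globally align two promoter sequences (affine gaps, deterministic)."""
    for name, seq in ((gene_a, seq_a), (gene_b, seq_b)):
        if not seq:
            raise ValueError(f"promoter sequence of {name!r} is empty")
        bad = set(seq.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"promoter of {name!r} has non-ACGTN characters {sorted(bad)}")
    ca, cb = encode(seq_a), encode(seq_b)
    score, a_pos, b_pos = global_affine_align(ca, cb)
    both = (a_pos >= 0) & (b_pos >= 0)
    match = np.zeros(len(a_pos), dtype=bool)
    ia = a_pos[both]
    ib = b_pos[both]
    eq = (ca[ia] == cb[ib]) & (ca[ia] < 4)  # N never matches
    match[both] = eq
    return PromoterAlignment(gene_a=gene_a, gene_b=gene_b, seq_a=seq_a,
                             seq_b=seq_b, a_pos=a_pos, b_pos=b_pos,
                             match=match, score=score)


def lift_interval(interval: tuple[int, int], aln: PromoterAlignment,
                  direction: str = "A->B",
                  min_lift: float = DEFAULT_MIN_LIFT) -> LiftResult:
    """Project ``interval`` (promoter offsets in the source member) through
    the alignment.

    ``lifted_fraction`` is the fraction of source bases with an aligned
    partner base; ``identity_in_region`` is the fraction of source bases
    sitting in match columns (so gaps count against it).  The target is
    ``None`` when ``lifted_fraction < min_lift``.
    """
    if direction == "A->B":
        src_pos, dst_pos, src_len = aln.a_pos, aln.b_pos, len(aln.seq_a)
    elif direction == "B->A":
        src_pos, dst_pos, src_len = aln.b_pos, aln.a_pos, len(aln.seq_b)
    else:
        raise ValueError(f"direction must be 'A->B' or 'B->A', got {direction!r}")
    start, end = interval
    if not (0 <= start < end <= src_len):
        raise ValueError(f"interval {interval} outside promoter [0,{src_len})")
    width = end - start
    in_iv = (src_pos >= start) & (src_pos < end)
    aligned = in_iv & (dst_pos >= 0)
    n_aligned = int(aligned.sum())
    lifted_fraction = n_aligned / width
    n_match = int((aligned & aln.match).sum())
    identity_in_region = n_match / width
    if lifted_fraction < min_lift or n_aligned == 0:
        return LiftResult(source=(start, end), target=None,
                          lifted_fraction=lifted_fraction,
                          identity_in_region=identity_in_region)
    partner = dst_pos[aligned]
    target = (int(partner.min()), int(partner.max()) + 1)
    return LiftResult(source=(start, end), target=target,
                      lifted_fraction=lifted_fraction,
                      identity_in_region=identity_in_region)
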