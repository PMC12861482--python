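"""Promoter variant calling from pairwise alignments.

Variants are read directly off the aligned columns of a homoeologous promoter
pair (member A = diploid, member B = tetraploid by pipeline convention):

* every mismatch column is one SNV (no MNV merging);
* every maximal run of gap columns in one sequence is a single InDel
  (run length 1-50 bp) or SV (run length > 50 bp); a run interrupted by an
  aligned column splits into separate events.

Positions are reported on member B (the tetraploid member of a
diploid-tetraploid pair); enough reference/alternate context is kept that
applying the variant list to sequence A reconstructs sequence B exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .liftover import PromoterAlignment

INDEL_MAX_LEN = 50  # gap runs longer than this are structural variants


@dataclass
class VariantRecord:
    """One alignment-derived variant.

    ``position`` is the offset on member B; for a deletion (bases of A absent
    from B) it is the B offset where the missing bases would insert.
    ``a_start`` is the corresponding offset on member A.  ``ref`` holds the
    member-A bases, ``alt`` the member-B bases (either may be empty).
    """

    vtype: str  # SNV | InDel | SV
    position: int
    length: int
    a_start: int
    ref: str
    alt: str
    overlaps_nonconserved_tfbs: bool = False

    @property
    def footprint(self) -> tuple[int, int]:
        """Half-open footprint on member-B coordinates."""
        return (self.position, self.position + self.length)


def _gap_type(length: int) -> str:
    return "InDel" if length <= INDEL_MAX_LEN else "SV"


def call_variants(aln: PromoterAlignment) -> list[VariantRecord]:
    """Call SNVs, InDels and SVs from the aligned columns of a promoter pair."""
    a_pos, b_pos, match = aln.a_pos, aln.b_pos, aln.match
    seq_a, seq_b = aln.seq_a, aln.seq_b
    out: list[VariantRecord] = []
    n = len(a_pos)
    i = 0
    next_b = 0  # B position of the next consumed B base (for deletion anchoring)
    while i < n:
        pa, pb = int(a_pos[i]), int(b_pos[i])
        if pa >= 0 and pb >= 0:
            if not match[i]:
                out.append(VariantRecord(vtype="SNV", position=pb, length=1,
                                         a_start=pa, ref=seq_a[pa], alt=seq_b[pb]))
            next_b = pb + 1
            i += 1
        elif pb < 0:  # gap in B: run of A bases deleted from B
            j = i
            while j < n and b_pos[j] < 0:
                j += 1
            run_a0 = int(a_pos[i])
            run_len = j - i
            out.append(VariantRecord(
                vtype=_gap_type(run_len), position=next_b, length=run_len,
                a_start=run_a0, ref=seq_a[run_a0:run_a0 + run_len], alt=""))
            i = j
        else:  # gap in A: run of B bases inserted in B
            j = i
            while j < n and a_pos[j] < 0:
                j += 1
            run_b0 = int(b_pos[i])
            run_len = j - i
            a_anchor = int(a_pos[j]) if j < n and a_pos[j] >= 0 else (
                int(a_pos[i - 1]) + 1 if i > 0 else 0)
            out.append(VariantRecord(
                vtype=_gap_type(run_len), position=run_b0, length=run_len,
                a_start=a_anchor, ref="", alt=seq_b[run_b0:run_b0 + run_len]))
            next_b = run_b0 + run_len
            i = j
    return out


def apply_variants(seq_a: str, variants: list[VariantRecord]) -> str:
    """Reconstruct member B by editing member A with the called variants.

    Used as the exactness oracle for :func:`call_variants`.
    """
    # process left-to-right on A; insertions at a given a_start apply before
    # the A base at that offset is copied
    events = sorted(variants, key=lambda v: (v.a_start, v.ref != ""))
    out: list[str] = []
    cursor = 0
    for v in events:
        if v.a_start < cursor:
            raise ValueError("overlapping variants")
        out.append(seq_a[cursor:v.a_start])
        cursor = v.a_start
        if v.vtype == "SNV":
            out.append(v.alt)
            cursor += 1
        elif v.ref:  # deletion of A bases
            cursor += len(v.ref)
        else:  # insertion of B bases
            out.append(v.alt)
    out.append(seq_a[cursor:])
    return "".join(out)


def overlap_with_tfbs(variants: list[VariantRecord],
                      hit_windows: list[tuple[int, int]],
                      conserved_flags: list[bool]) -> dict[str, float]:
    """Annotate variants overlapping nonconserved TFBS windows (>=1 bp of the
    variant footprint intersects a nonconserved hit window, half-open) and
    return the per-type overlap fractions.

    ``hit_windows`` are motif-hit intervals on the same member-B promoter
    coordinates as the variant positions; ``conserved_flags`` mark, per hit,
    whether the TFBS is conserved in the homoeologous promoter.
    """
    if len(hit_windows) != len(conserved_flags):
        raise ValueError("hit_windows and conserved_flags length mismatch")
    noncons = [w for w, c in zip(hit_windows, conserved_flags) if not c]
    for v in variants:
        s, e = v.footprint
        e = max(e, s + 1)  # zero-length deletion anchors still occupy a point
        v.overlaps_nonconserved_tfbs = any(s < we and ws < e for ws, we in noncons)
    fractions: dict[str, float] = {}
    for vtype in ("SNV", "InDel", "SV"):
        of_type = [v for v in variants if v.vtype == vtype]
        if of_type:
            fractions[vtype] = sum(v.overlaps_nonconserved_tfbs for v in of_type) / len(of_type)
        else:
            fractions[vtype] = float("nan")
    return fractions


def variation_length_vs_cs(total_variant_length: dict[str, float],
                           conservation_scores: dict[str, float]) -> tuple[float, float]:
    """Spearman correlation between per-gene total variant length and TFBS
    conservation score.  Returns ``(rho, p_value)``."""
    genes = sorted(set(total_variant_length) & set(conservation_scores))
    if len(genes) < 3:
        raise ValueError("need at least 3 genes with both quantities")
    x = np.array([total_variant_length[g] for g in genes], dtype=float)
    y = np.array([conservation_scores[g] for g in genes], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero variance in input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
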