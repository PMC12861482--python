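"""Per-pair, per-mark conservation calls for promoter peaks.

For a homoeologous pair, a mark's promoter peaks are judged on two layers:

* sequence conservation: every promoter peak (in whichever member has peaks)
  lifts onto the partner promoter with lifted_fraction >= ``min_lift`` and
  per-base identity >= ``min_identity`` inside the peak footprint;
* epigenome conservation: at least one successfully lifted peak region is
  covered >= ``min_peak_overlap`` by a same-mark peak in the partner
  promoter (either direction suffices).

The two booleans map onto the three-class scheme: Class I = both conserved,
Class II = sequence only, Class III = neither.  A pair that is epigenome-
conserved on a divergent sequence does not fit the scheme and is reported as
``unclassified``; pairs without any promoter peak of the mark are
``no_peak``.  Both of the latter are excluded from class proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .liftover import PromoterAlignment, lift_interval

DEFAULT_MIN_LIFT = 0.5
DEFAULT_MIN_IDENTITY = 0.7
DEFAULT_MIN_PEAK_OVERLAP = 0.5

KLASS_I = "I"
KLASS_II = "II"
KLASS_III = "III"
KLASS_UNCLASSIFIED = "unclassified"
KLASS_NO_PEAK = "no_peak"


@dataclass
class PairCall:
    tetrad_id: str
    pair: str
    mark: str
    seq_conserved: bool
    epi_conserved: bool
    klass: str
    n_peaks_a: int = 0
    n_peaks_b: int = 0


def _klass(seq: bool, epi: bool) -> str:
    if seq and epi:
        return KLASS_I
    if seq and not epi:
        return KLASS_II
    if not seq and not epi:
        return KLASS_III
    return KLASS_UNCLASSIFIED


def _covered_fraction(target: tuple[int, int], peaks: list[tuple[int, int]]) -> float:
    """Fraction of ``target`` covered by the union of ``peaks`` (half-open)."""
    s, e = target
    if e <= s:
        return 0.0
    merged: list[list[int]] = []
    for ps, pe in sorted(p for p in peaks):
        cs, ce = max(ps, s), min(pe, e)
        if cs >= ce:
            continue
        if merged and cs <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], ce)
        else:
            merged.append([cs, ce])
    covered = sum(ce - cs for cs, ce in merged)
    return covered / (e - s)


def call_peak_conservation(tetrad_id: str, pair: str, mark: str,
                           peaks_a: list[tuple[int, int]],
                           peaks_b: list[tuple[int, int]],
                           aln: PromoterAlignment,
                           min_lift: float = DEFAULT_MIN_LIFT,
                           min_identity: float = DEFAULT_MIN_IDENTITY,
                           min_peak_overlap: float = DEFAULT_MIN_PEAK_OVERLAP,
                           seq_requires_all: bool = True,
                           epi_requires_all: bool = False) -> PairCall:
    """Call sequence and epigenome conservation for one pair and mark.

    ``peaks_a``/``peaks_b`` are the mark's peaks already intersected with the
    two promoters, in promoter coordinates.  ``aln`` is the pair's promoter
    alignment (member A first).
    """
    if aln is None:
        raise ValueError(f"missing promoter alignment for tetrad {tetrad_id} pair {pair}")
    if not peaks_a and not peaks_b:
        return PairCall(tetrad_id, pair, mark, False, False, KLASS_NO_PEAK, 0, 0)

    seq_flags: list[bool] = []
    epi_flags: list[bool] = []
    for direction, own_peaks, partner_peaks in (
            ("A->B", peaks_a, peaks_b), ("B->A", peaks_b, peaks_a)):
        for iv in own_peaks:
            lift = lift_interval(iv, aln, direction=direction, min_lift=min_lift)
            ok = lift.target is not None and lift.identity_in_region >= min_identity
            seq_flags.append(ok)
            if lift.target is not None:
                epi_flags.append(
                    _covered_fraction(lift.target, partner_peaks) >= min_peak_overlap)
            else:
                epi_flags.append(False)

    seq_conserved = all(seq_flags) if seq_requires_all else any(seq_flags)
    epi_conserved = all(epi_flags) if epi_requires_all else any(epi_flags)
    return PairCall(tetrad_id, pair, mark, seq_conserved, epi_conserved,
                    _klass(seq_conserved, epi_conserved),
                    len(peaks_a), len(peaks_b))


def class_proportions(calls: list[PairCall], pair: str, mark: str) -> dict:
    """Counts and proportions of Classes I/II/III for one pair and mark.

    ``no_peak`` and ``unclassified`` calls are excluded from the denominator.
    """
    selected = [c for c in calls if c.pair == pair and c.mark == mark
                and c.klass in (KLASS_I, KLASS_II, KLASS_III)]
    n = len(selected)
    if n == 0:
        raise ValueError(f"no classifiable calls for pair {pair!r} mark {mark!r}")
    counts = {k: sum(c.klass == k for c in selected)
              for k in (KLASS_I, KLASS_II, KLASS_III)}
    return {"pair": pair, "mark": mark, "n": n, "counts": counts,
            "proportions": {k: v / n for k, v in counts.items()}}
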