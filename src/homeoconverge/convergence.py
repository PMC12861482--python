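"""Convergence categorisation between the tetraploid subgenome pair (An-Cn)
and the diploid progenitor pair (Ar-Co).

For each mark and tetrad whose An-Cn feature is conserved, the Ar-Co status
assigns one of three categories:

* ``same`` - the feature is conserved in Ar-Co as well;
* ``convergent`` - Ar-Co has promoter peak(s) of the mark but the feature is
  not conserved there (the tetraploid subgenomes converged);
* ``others`` - no promoter peak of the mark was detected in Ar-Co.

The epigenomic layer conditions on An-Cn epigenome conservation, the
sequence layer on An-Cn sequence conservation (Class I or II).  Expression
convergence is a per-tetrad call: the An-Cn fold change falls below a
threshold that the Ar-Co fold change reaches (|log2FC| with pseudocount 1).
"""

from __future__ import annotations

from dataclasses import dataclass

from .expression import DEFAULT_EPS, log2_fold_change
from .peak_conservation import KLASS_NO_PEAK, PairCall

CATEGORY_SAME = "same"
CATEGORY_CONVERGENT = "convergent"
CATEGORY_OTHERS = "others"


@dataclass
class ConvergenceCall:
    tetrad_id: str
    mark: str
    layer: str  # 'epigenomic' | 'sequence'
    category: str


def _categorise(ar_co: PairCall, conserved_in_diploids: bool) -> str:
    if ar_co.klass == KLASS_NO_PEAK:
        return CATEGORY_OTHERS
    return CATEGORY_SAME if conserved_in_diploids else CATEGORY_CONVERGENT


def call_epigenomic_convergence(an_cn_calls: dict[str, PairCall],
                                ar_co_calls: dict[str, PairCall],
                                mark: str) -> list[ConvergenceCall]:
    """Categorise tetrads with An-Cn epigenome conservation by their Ar-Co
    epigenome status.  Inputs map tetrad_id -> PairCall for one mark."""
    out = []
    for tid, an_cn in an_cn_calls.items():
        if tid not in ar_co_calls:
            raise KeyError(f"tetrad {tid!r} missing from Ar-Co calls")
        if not an_cn.epi_conserved:
            continue
        ar_co = ar_co_calls[tid]
        out.append(ConvergenceCall(tid, mark, "epigenomic",
                                   _categorise(ar_co, ar_co.epi_conserved)))
    return out


def call_sequence_convergence(an_cn_calls: dict[str, PairCall],
                              ar_co_calls: dict[str, PairCall],
                              mark: str) -> list[ConvergenceCall]:
    """Categorise tetrads with An-Cn sequence conservation (Class I or II)
    by their Ar-Co sequence status."""
    out = []
    for tid, an_cn in an_cn_calls.items():
        if tid not in ar_co_calls:
            raise KeyError(f"tetrad {tid!r} missing from Ar-Co calls")
        if an_cn.klass == KLASS_NO_PEAK or not an_cn.seq_conserved:
            continue
        ar_co = ar_co_calls[tid]
        conserved = ar_co.klass != KLASS_NO_PEAK and ar_co.seq_conserved
        out.append(ConvergenceCall(tid, mark, "sequence",
                                   _categorise(ar_co, conserved)))
    return out


def category_summary(calls: list[ConvergenceCall]) -> dict[str, int]:
    counts = {CATEGORY_SAME: 0, CATEGORY_CONVERGENT: 0, CATEGORY_OTHERS: 0}
    for c in calls:
        counts[c.category] += 1
    return counts


def call_expression_convergence(tpm_ar: float, tpm_co: float,
                                tpm_an: float, tpm_cn: float,
                                fc_threshold: float = 1.0,
                                eps: float = DEFAULT_EPS) -> bool:
    """Expression convergence: the subgenome pair's divergence is below the
    fold-change threshold while the progenitor pair's is at or above it."""
    for tpm in (tpm_ar, tpm_co, tpm_an, tpm_cn):
        if tpm < 0:
            raise ValueError("TPM values must be nonnegative")
    fc_tetraploid = log2_fold_change(tpm_an, tpm_cn, eps=eps)
    fc_diploid = log2_fold_change(tpm_ar, tpm_co, eps=eps)
    return fc_tetraploid < fc_threshold and fc_diploid >= fc_threshold
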