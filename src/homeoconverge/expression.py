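"""Expression-divergence metrics and the contingency statistics used by the
pipeline summaries.

Expression divergence between homoeologs is log2((max TPM + eps)/(min TPM +
eps)) with a pseudocount of 1 by default, so a TPM of zero never produces an
infinite fold change.  Absolute TPM differences are binned into the half-open
classes [0,1), [1,5), [5,10), [10,inf).  2x2 contingency tables use the
Pearson chi-square with Yates continuity correction by default; p-values
below 2.2e-16 are reported with that floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_EPS = 1.0
TPM_DIFF_BIN_EDGES = (0.0, 1.0, 5.0, 10.0)
TPM_DIFF_BIN_LABELS = ("0-1", "1-5", "5-10", ">10")
P_FLOOR = 2.2e-16


@dataclass
class ContingencyResult:
    table: np.ndarray
    chi2: float
    p_value: float
    correction: bool

    @property
    def p_label(self) -> str:
        return format_p(self.p_value)


def format_p(p: float) -> str:
    """Report p-values below 2.2e-16 as '<2.2e-16' (R's printed floor)."""
    return "<2.2e-16" if p < P_FLOOR else f"{p:.3g}"


def log2_fold_change(tpm_a: float, tpm_b: float, eps: float = DEFAULT_EPS) -> float:
    """log2((max + eps)/(min + eps)); symmetric and nonnegative."""
    if tpm_a < 0 or tpm_b < 0:
        raise ValueError("TPM values must be nonnegative")
    hi, lo = max(tpm_a, tpm_b), min(tpm_a, tpm_b)
    return float(np.log2((hi + eps) / (lo + eps)))


def tpm_diff_bin(diff: float) -> str:
    """Bin one absolute TPM difference into [0,1), [1,5), [5,10), [10,inf)."""
    if diff < 0:
        raise ValueError("absolute difference cannot be negative")
    for edge, label in zip(TPM_DIFF_BIN_EDGES[1:], TPM_DIFF_BIN_LABELS[:-1]):
        if diff < edge:
            return label
    return TPM_DIFF_BIN_LABELS[-1]


def tpm_diff_bins(tpm_pairs: list[tuple[float, float]]) -> dict[str, int]:
    """Count homoeolog pairs per absolute-TPM-difference bin."""
    counts = {label: 0 for label in TPM_DIFF_BIN_LABELS}
    for a, b in tpm_pairs:
        counts[tpm_diff_bin(abs(a - b))] += 1
    return counts


def chi_square_2x2(table, correction: bool = True) -> ContingencyResult:
    """Pearson chi-square on a 2x2 table, Yates-corrected by default."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("all table margins must be positive")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=correction)
    return ContingencyResult(table=arr.astype(int), chi2=float(chi2),
                             p_value=float(p), correction=correction)


def deg_filter(log2fc, p_values, fc_threshold: float = 1.0,
               p_threshold: float = 0.05) -> np.ndarray:
    """DEG flags: p < 0.05 and |log2FC| > 1 (both strict)."""
    fc = np.asarray(log2fc, dtype=float)
    p = np.asarray(p_values, dtype=float)
    if fc.shape != p.shape:
        raise ValueError("fold-change and p-value vectors differ in length")
    return (p < p_threshold) & (np.abs(fc) > fc_threshold)


def marked_gene_shift(count_diploid: int, count_tetraploid: int,
                      denominator: int) -> float:
    """Signed percentage shift in marked-gene counts, with the tetrad total as
    denominator: (tetraploid - diploid) / denominator * 100."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if count_diploid > denominator or count_tetraploid > denominator:
        raise ValueError("counts cannot exceed the denominator")
    return (count_tetraploid - count_diploid) / denominator * 100.0


def proportion_percent(count: int, total: int) -> float:
    """count/total as a percentage (the 'x% (count in total)' reporting form)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return count / total * 100.0


def signal_expression_correlation(signal, tpm) -> tuple[float, float]:
    """Pearson r between per-gene promoter peak signal and log2(TPM + 1).

    Returns ``(r, p_value)``.  Requires n >= 3 and nonzero variance.
    """
    x = np.asarray(signal, dtype=float)
    y = np.log2(np.asarray(tpm, dtype=float) + 1.0)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("signal and expression must be 1-D and equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 genes")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def expression_divergence_test(group_a, group_b,
                               alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U comparison of two |log2FC| distributions (the rank test
    behind the class-wise divergence comparisons).  Returns (U, p)."""
    u, p = stats.mannwhitneyu(group_a, group_b, alternative=alternative)
    return float(u), float(p)
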