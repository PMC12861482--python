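import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from homeoconverge.expression import (chi_square_2x2, deg_filter, format_p,
                                      log2_fold_change, marked_gene_shift,
                                      proportion_percent,
                                      signal_expression_correlation,
                                      tpm_diff_bins)


def closed_form_chi2(a, b, c, d, yates):
    """Textbook 2x2 formula, independent of scipy."""
    a, b, c, d = float(a), float(b), float(c), float(d)
    n = a + b + c + d
    num = abs(a * d - b * c)
    if yates:
        num = max(0.0, num - n / 2)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    return n * num ** 2 / denom


@pytest.mark.parametrize("pair,eps,expected", [
    ((8, 2), 0.0, 2.0),
    ((2, 8), 0.0, 2.0),
    ((7.3, 7.3), 1.0, 0.0),
    ((0, 3), 1.0, 2.0),
])
def test_log2_fold_change_examples(pair, eps, expected):
    assert log2_fold_change(*pair, eps=eps) == pytest.approx(expected)


@given(st.floats(0, 1e5), st.floats(0, 1e5))
@settings(derandomize=True, max_examples=50)
def test_log2_fold_change_symmetric_nonnegative(a, b):
    fc = log2_fold_change(a, b)
    assert fc == log2_fold_change(b, a)
    assert fc >= 0
    if a == b:
        assert fc == 0


def test_log2_fold_change_rejects_negative():
    with pytest.raises(ValueError):
        log2_fold_change(-1, 2)


def test_tpm_diff_bins_boundaries():
    pairs = [(0, 0.5), (0, 1.0), (0, 5.0), (0, 10.0), (0, 12.0)]
    counts = tpm_diff_bins(pairs)
    assert counts == {"0-1": 1, "1-5": 1, "5-10": 1, ">10": 2}
    assert sum(counts.values()) == len(pairs)


def test_tpm_diff_bins_uniform_measure():
    """Uniform(0,20) differences split 1:4:5:10 across the bins."""
    rng = np.random.default_rng(42)
    diffs = rng.uniform(0, 20, 10_000)
    counts = tpm_diff_bins([(0.0, d) for d in diffs])
    fracs = {k: v / 10_000 for k, v in counts.items()}
    assert fracs["0-1"] == pytest.approx(0.05, abs=0.02)
    assert fracs["1-5"] == pytest.approx(0.20, abs=0.02)
    assert fracs["5-10"] == pytest.approx(0.25, abs=0.02)
    assert fracs[">10"] == pytest.approx(0.50, abs=0.02)


def test_chi_square_matches_printed_statistic():
    res = chi_square_2x2([[4809, 14748 - 4809], [3437, 14748 - 3437]])
    assert round(res.chi2, 1) == 316.4
    assert res.p_label == "<2.2e-16"
    uncorrected = chi_square_2x2([[4809, 9939], [3437, 11311]], correction=False)
    assert round(uncorrected.chi2, 1) == 316.9


def test_chi_square_flat_table_is_zero():
    assert chi_square_2x2([[10, 10], [10, 10]]).chi2 == 0.0


@given(st.integers(1, 5000), st.integers(1, 5000),
       st.integers(1, 5000), st.integers(1, 5000), st.booleans())
@settings(derandomize=True, max_examples=200)
def test_chi_square_equals_closed_form(a, b, c, d, yates):
    res = chi_square_2x2([[a, b], [c, d]], correction=yates)
    assert res.chi2 == pytest.approx(closed_form_chi2(a, b, c, d, yates))
    if yates:
        assert res.chi2 <= chi_square_2x2([[a, b], [c, d]], correction=False).chi2 + 1e-12


def test_chi_square_rejects_zero_margin():
    with pytest.raises(ValueError):
        chi_square_2x2([[0, 0], [5, 5]])


def test_deg_filter_boundaries_and_loop_oracle():
    assert not deg_filter([1.0], [0.01])[0]   # |log2FC| must exceed 1 strictly
    assert deg_filter([2.0], [0.049])[0]
    assert not deg_filter([2.0], [0.05])[0]   # p must be below 0.05 strictly
    rng = np.random.default_rng(0)
    fc = rng.normal(0, 2, 500)
    p = rng.uniform(0, 0.1, 500)
    flags = deg_filter(fc, p)
    loop = sum(1 for f, q in zip(fc, p) if q < 0.05 and abs(f) > 1)
    assert flags.sum() == loop
    with pytest.raises(ValueError):
        deg_filter([1.0, 2.0], [0.01])


@pytest.mark.parametrize("dip,tet,expected", [
    (8970, 7788, -8.0), (4190, 5142, 6.5), (8290, 9238, 6.4),
    (8660, 9588, 6.3), (5000, 5000, 0.0),
])
def test_marked_gene_shift_printed_values(dip, tet, expected):
    assert round(marked_gene_shift(dip, tet, 14748), 1) == expected


@pytest.mark.parametrize("count,total,expected", [
    (4809, 14748, 32.6), (3437, 14748, 23.3),
    (1911, 8333, 22.9), (2967, 8333, 35.6), (3455, 8333, 41.5),
])
def test_proportion_printed_values(count, total, expected):
    assert round(proportion_percent(count, total), 1) == expected


def test_signal_expression_correlation():
    expr = np.arange(1.0, 51.0)
    r, _ = signal_expression_correlation(2 * np.log2(expr + 1), expr)
    assert r == pytest.approx(1.0)
    rng = np.random.default_rng(7)
    r_null, _ = signal_expression_correlation(rng.normal(size=10_000),
                                              rng.uniform(0, 50, 10_000))
    assert abs(r_null) < 0.05
    with pytest.raises(ValueError):
        signal_expression_correlation([1.0, 1.0, 1.0], [2.0, 3.0, 4.0])


def test_format_p_floor():
    assert format_p(1e-300) == "<2.2e-16"
    assert format_p(0.03) == "0.03"
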