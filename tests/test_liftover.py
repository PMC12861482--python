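import numpy as np
import pytest

from homeoconverge._aligner import encode, global_affine_align
from homeoconverge.io_formats import GeneModel, GenomeAssembly
from homeoconverge.liftover import (align_promoters, extract_promoter,
                                    lift_interval, reverse_complement)


def brute_affine_score(a, b, match=2, mismatch=-3, go=-5, ge=-2):
    """Full-matrix three-state DP, kept independent of the jitted kernel."""
    NEG = -1e30
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Y[0][j] = go + (j - 1) * ge
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(max(M[i - 1][j], X[i - 1][j], Y[i - 1][j]) + go,
                          X[i - 1][j] + ge)
            Y[i][j] = max(max(M[i][j - 1], X[i][j - 1], Y[i][j - 1]) + go,
                          Y[i][j - 1] + ge)
    return max(M[n][m], X[n][m], Y[n][m])


@pytest.fixture
def assembly():
    rng = np.random.default_rng(0)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10000)])
    return GenomeAssembly(label="Ar", sequences={"c1": seq})


def test_extract_promoter_plus_strand(assembly):
    gene = GeneModel("g", "c1", "+", 5000, (5000, 5600))
    prom = extract_promoter(gene, assembly)
    assert prom.interval == (3500, 5500)
    assert prom.sequence == assembly.sequences["c1"][3500:5500]
    assert not prom.clipped


def test_extract_promoter_minus_strand_reverse_complements(assembly):
    gene = GeneModel("g", "c1", "-", 5000, (4500, 5001))
    prom = extract_promoter(gene, assembly)
    assert prom.interval == (4500, 6500)
    assert prom.sequence == reverse_complement(assembly.sequences["c1"][4500:6500])


def test_extract_promoter_clipped_at_chromosome_start(assembly):
    gene = GeneModel("g", "c1", "+", 100, (100, 700))
    prom = extract_promoter(gene, assembly)
    assert prom.interval == (0, 600)
    assert prom.clipped


def test_promoter_coordinate_maps_invert(assembly):
    gene = GeneModel("g", "c1", "-", 5000, (4500, 5001))
    prom = extract_promoter(gene, assembly)
    assert prom.to_genome_coords(*prom.to_promoter_coords(4600, 4700)) == (4600, 4700)


def test_align_identical_sequences():
    seq = "ACGT" * 25
    aln = align_promoters(seq, seq)
    assert aln.identity == 1.0
    assert aln.coverage_a == aln.coverage_b == 1.0


def test_align_single_substitution_gives_one_mismatch_column():
    rng = np.random.default_rng(1)
    a = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
    b = a[:50] + ("A" if a[50] != "A" else "C") + a[51:]
    aln = align_promoters(a, b)
    mismatches = (~aln.match) & (aln.a_pos >= 0) & (aln.b_pos >= 0)
    assert mismatches.sum() == 1
    assert aln.a_pos[np.nonzero(mismatches)[0][0]] == 50


def test_align_rejects_empty_and_bad_characters():
    with pytest.raises(ValueError):
        align_promoters("", "ACGT")
    with pytest.raises(ValueError):
        align_promoters("ACGU", "ACGT")


def test_aligner_score_matches_full_matrix_dp():
    rng = np.random.default_rng(2)
    bases = np.array(list("ACGTN"))
    for _ in range(10):
        la, lb = rng.integers(20, 120, 2)
        a = "".join(bases[rng.integers(0, 5, la)])
        b = "".join(bases[rng.integers(0, 4, lb)])
        score, _, _ = global_affine_align(encode(a), encode(b))
        assert score == pytest.approx(brute_affine_score(a, b))


def test_lift_identity_roundtrip_exhaustive():
    """On identical 50-mers every sub-interval lifts to itself and back."""
    seq = "ACGTGTTACGGATCAGGCATTACGATCAGGACTTACGGAATTCCAGGATT"
    aln = align_promoters(seq, seq)
    for s in range(len(seq)):
        for e in range(s + 1, len(seq) + 1):
            fwd = lift_interval((s, e), aln, "A->B")
            assert fwd.target == (s, e)
            assert fwd.lifted_fraction == 1.0
            back = lift_interval(fwd.target, aln, "B->A")
            assert back.target == (s, e)


def test_lift_interval_inside_deletion_is_null():
    rng = np.random.default_rng(3)
    a = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
    b = a[:100] + a[160:]  # 60 bp deleted from B
    aln = align_promoters(a, b)
    res = lift_interval((110, 150), aln, "A->B")
    assert res.target is None
    assert res.lifted_fraction == 0.0


def test_lift_interval_straddling_insertion_widens():
    rng = np.random.default_rng(4)
    a = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
    ins = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10)])
    b = a[:100] + ins + a[100:]  # 10 bp inserted in B
    aln = align_promoters(a, b)
    res = lift_interval((90, 110), aln, "A->B")
    assert res.lifted_fraction == 1.0
    assert res.target is not None
    assert (res.target[1] - res.target[0]) == 20 + 10


def test_lifted_fraction_monotone_in_gap_burden():
    """Growing a deletion inside the query interval never raises the lifted
    fraction."""
    rng = np.random.default_rng(5)
    a = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
    fractions = []
    for cut in (0, 10, 30, 60, 90):
        b = a[:150] + a[150 + cut:]
        aln = align_promoters(a, b)
        fractions.append(lift_interval((100, 250), aln, "A->B",
                                       min_lift=0.0).lifted_fraction)
    assert all(x >= y for x, y in zip(fractions, fractions[1:]))


def test_lift_interval_outside_promoter_errors():
    aln = align_promoters("ACGTACGT", "ACGTACGT")
    with pytest.raises(ValueError):
        lift_interval((4, 20), aln, "A->B")
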