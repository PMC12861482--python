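import numpy as np
import pytest

from homeoconverge.liftover import reverse_complement
from homeoconverge.synthetic_data import _load_packaged_motifs
from homeoconverge.tfbs import (PWM, ConservationScore,
                                high_conservation_fraction, MotifHit,
                                normalize_counts, read_jaspar, scan_promoter,
                                scan_promoter_all, scan_promoter_bruteforce,
                                target_count_comparison, tf_target_counts,
                                tfbs_conservation_score)

BASES = np.array(list("ACGT"))


@pytest.fixture(scope="module")
def library():
    return _load_packaged_motifs()


def _random_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


def test_packaged_library_well_formed(library):
    assert len(library) >= 10
    for pwm in library:
        assert pwm.length >= 4
        np.testing.assert_allclose(pwm.matrix.sum(axis=0), 1.0, atol=1e-9)
        assert pwm.max_score() > 10  # consensus is always detectable


def test_consensus_scores_at_maximum(library):
    rng = np.random.default_rng(0)
    for pwm in library[:4]:
        seq = _random_seq(rng, 60) + pwm.consensus + _random_seq(rng, 60)
        hits = scan_promoter(seq, pwm)
        best = max(hits, key=lambda h: h.log_odds)
        assert best.offset == 60 and best.strand == "+"
        assert best.log_odds == pytest.approx(pwm.max_score())


def test_uniform_pwm_scores_zero_everywhere():
    pwm = PWM("uniform", np.full((4, 8), 0.25))
    assert scan_promoter("ACGT" * 20, pwm, threshold=0.0) == []
    # log-odds of every window is exactly zero
    brute = scan_promoter_bruteforce("ACGT" * 20, pwm, threshold=-0.001)
    assert all(h.log_odds == pytest.approx(0.0) for h in brute)


def test_reverse_complement_hits_on_minus_strand(library):
    rng = np.random.default_rng(1)
    pwm = library[0]
    seq = _random_seq(rng, 50) + reverse_complement(pwm.consensus) + _random_seq(rng, 50)
    hits = scan_promoter(seq, pwm)
    best = max(hits, key=lambda h: h.log_odds)
    assert best.strand == "-" and best.offset == 50
    assert best.log_odds == pytest.approx(pwm.max_score())


def test_windows_containing_n_are_skipped(library):
    pwm = library[0]
    seq = pwm.consensus[:5] + "N" + pwm.consensus[6:]
    assert scan_promoter(seq, pwm, threshold=-1e9) == []


def test_scanner_matches_bruteforce(library):
    rng = np.random.default_rng(2)
    for seed in range(3):
        seq = list(_random_seq(rng, 400))
        pwm = library[seed % len(library)]
        # implant a noisy instance so there is signal, plus an N
        inst = list(pwm.consensus)
        inst[3] = "T" if inst[3] != "T" else "A"
        seq[100:100 + len(inst)] = inst
        seq[350] = "N"
        seq = "".join(seq)
        fast = scan_promoter(seq, pwm, threshold=5.0)
        brute = scan_promoter_bruteforce(seq, pwm, threshold=5.0)
        assert [(h.offset, h.strand) for h in fast] == \
            [(h.offset, h.strand) for h in brute]
        for hf, hb in zip(fast, brute):
            assert hf.log_odds == pytest.approx(hb.log_odds)


def test_batched_scan_equals_per_motif_scan(library):
    rng = np.random.default_rng(3)
    seq = _random_seq(rng, 300) + library[1].consensus + _random_seq(rng, 300)
    merged = []
    for pwm in library:
        merged.extend(scan_promoter(seq, pwm, threshold=8.0))
    merged.sort(key=lambda h: (h.motif_id, h.offset, h.strand))
    batched = scan_promoter_all(seq, library, threshold=8.0)
    assert [(h.motif_id, h.offset, h.strand) for h in batched] == \
        [(h.motif_id, h.offset, h.strand) for h in merged]
    for hb, hm in zip(batched, merged):
        assert hb.log_odds == pytest.approx(hm.log_odds)


def test_jaspar_round_trip(tmp_path):
    text = ">M1 test\nA [ 10 0 ]\nC [ 0 10 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
    p = tmp_path / "m.jaspar"
    p.write_text(text)
    with pytest.raises(ValueError):
        read_jaspar(p)  # L < 4
    text2 = ">M1 test\n" + "\n".join(
        f"{b} [ " + " ".join(["10" if b == c else "0" for c in "ACGT"]) + " ]"
        for b in "ACGT")
    p.write_text(text2)
    pwms = read_jaspar(p)
    assert pwms[0].consensus == "ACGT"


def _hit(motif, gene="g", offset=0):
    return MotifHit(motif_id=motif, gene_id=gene, offset=offset, strand="+",
                    log_odds=12.0, length=10)


def test_conservation_score_identical_promoters(library):
    rng = np.random.default_rng(4)
    seq = _random_seq(rng, 200) + library[2].consensus + _random_seq(rng, 200)
    hits = scan_promoter_all(seq, library)
    score = tfbs_conservation_score(hits, hits)
    assert score.cs == 1.0


def test_conservation_score_counting_oracle():
    tet = [_hit("m1"), _hit("m2"), _hit("m3"), _hit("m4")]
    dip = [_hit("m1"), _hit("m9")]
    score = tfbs_conservation_score(tet, dip)
    assert (score.n_total, score.n_conserved) == (4, 1)
    assert score.cs == 0.25


def test_position_matched_mode_requires_lifted_overlap():
    from homeoconverge.liftover import align_promoters
    rng = np.random.default_rng(5)
    seq = _random_seq(rng, 300)
    aln = align_promoters(seq, seq)
    tet = [MotifHit("m1", "g", 50, "+", 12.0, length=10)]
    same_pos = [MotifHit("m1", "g", 50, "+", 12.0, length=10)]
    far_pos = [MotifHit("m1", "g", 200, "+", 12.0, length=10)]
    # identity mode: conserved either way; positional mode: only when windows meet
    assert tfbs_conservation_score(tet, far_pos).cs == 1.0
    assert tfbs_conservation_score(tet, same_pos, position_matched=True,
                                   aln=aln).cs == 1.0
    assert tfbs_conservation_score(tet, far_pos, position_matched=True,
                                   aln=aln).cs == 0.0
    with pytest.raises(ValueError):
        tfbs_conservation_score(tet, same_pos, position_matched=True)


def test_conservation_score_null_when_no_hits():
    assert tfbs_conservation_score([], [_hit("m1")]).cs is None


def test_cs_monotone_under_tetraploid_only_gains():
    dip = [_hit("m1")]
    tet = [_hit("m1")]
    last = 1.0
    for extra in ("m2", "m3", "m4"):
        tet = tet + [_hit(extra)]
        cs = tfbs_conservation_score(tet, dip).cs
        assert cs <= last
        last = cs


def test_high_conservation_fraction_strict_cutoff():
    scores = [ConservationScore("g", 100, int(c * 100)) for c in (0.2, 0.61, 1.0)]
    assert high_conservation_fraction(scores) == pytest.approx(2 / 3)
    flat = [ConservationScore("g", 10, 6)] * 5
    assert high_conservation_fraction(flat) == 0.0  # cs == cutoff not counted
    with pytest.raises(ValueError):
        high_conservation_fraction([ConservationScore("g", 0, 0)])


def test_tf_target_counts_and_comparison():
    hits = {g: [_hit("m1", "g1"), _hit("m1", "g2"), _hit("m2", "g1")]
            for g in ("Ar", "Co", "An", "Cn")}
    genes = {g: {"g1", "g2"} for g in ("Ar", "Co", "An", "Cn")}
    counts = tf_target_counts(hits, genes)
    assert counts.loc["m1"].tolist() == [2, 2, 2, 2]
    comps = target_count_comparison(counts)
    assert all(c["r"] == pytest.approx(1.0) and c["slope"] == pytest.approx(1.0)
               for c in comps)
    # doubling the y-side counts doubles the slope
    counts2 = counts.copy()
    counts2["An"] = [4, 2]
    counts2.loc["m2", "Ar"] = 0  # make x vary: m1->2, m2->0... keep simple
    counts2.loc["m1", "Ar"] = 2
    comp = target_count_comparison(counts2, pairs=(("Ar", "An"),))[0]
    assert comp["slope"] == pytest.approx(
        np.polyfit(counts2["Ar"], counts2["An"], 1)[0])


def test_tf_target_counts_requires_two_motifs():
    hits = {g: [_hit("m1", "g1")] for g in ("Ar", "Co", "An", "Cn")}
    genes = {g: {"g1"} for g in ("Ar", "Co", "An", "Cn")}
    with pytest.raises(ValueError):
        tf_target_counts(hits, genes)
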