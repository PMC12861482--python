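import numpy as np
import pytest

from homeoconverge.tetrads import (AnchorPair, GeneSeq, assemble_tetrads,
                                   best_hits, collinear_chains)

BASES = np.array(list("ACGT"))


def _random_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


def _mutate(rng, seq, rate):
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[i] = "ACGT"[(("ACGT".index(out[i])) + rng.integers(1, 4)) % 4]
    return "".join(out)


def test_identical_single_gene_sets():
    rng = np.random.default_rng(0)
    seq = _random_seq(rng, 500)
    a = [GeneSeq("a1", "c1", 0, seq)]
    b = [GeneSeq("b1", "c1", 0, seq)]
    pairs = best_hits(a, b)
    assert len(pairs) == 1
    assert pairs[0].cscore == 1.0
    assert not pairs[0].ambiguous


def test_tie_broken_lexicographically_and_flagged():
    rng = np.random.default_rng(1)
    seq = _random_seq(rng, 400)
    a = [GeneSeq("a1", "c1", 0, seq)]
    b = [GeneSeq("b2", "c1", 0, seq), GeneSeq("b1", "c1", 1, seq)]
    pairs = best_hits(a, b)
    assert len(pairs) == 1
    assert pairs[0].gene_b == "b1"
    assert pairs[0].ambiguous


def test_best_hits_rejects_empty():
    with pytest.raises(ValueError):
        best_hits([], [GeneSeq("b", "c", 0, "ACGT" * 100)])


def test_best_hits_recovers_true_pairs_under_mutation():
    rng = np.random.default_rng(2)
    seqs = [_random_seq(rng, 800) for _ in range(20)]
    a = [GeneSeq(f"a{i:02d}", "c1", i, s) for i, s in enumerate(seqs)]
    b = [GeneSeq(f"b{i:02d}", "c1", i, _mutate(rng, s, 0.05))
         for i, s in enumerate(seqs)]
    pairs = best_hits(a, b)
    assert len(pairs) == 20
    assert all(p.gene_a[1:] == p.gene_b[1:] for p in pairs)


def _diagonal_pairs(n, chrom="c1"):
    pairs = [AnchorPair(f"a{i}", f"b{i}", 100.0, 1.0) for i in range(n)]
    oa = {f"a{i}": (chrom, i) for i in range(n)}
    ob = {f"b{i}": (chrom, i) for i in range(n)}
    return pairs, oa, ob


def test_collinear_block_fully_kept():
    pairs, oa, ob = _diagonal_pairs(10)
    assert len(collinear_chains(pairs, oa, ob)) == 10


def test_isolated_off_diagonal_pair_dropped():
    pairs, oa, ob = _diagonal_pairs(10)
    pairs.append(AnchorPair("ax", "bx", 100.0, 1.0))
    oa["ax"] = ("c1", 30)
    ob["bx"] = ("c1", 80)
    kept = collinear_chains(pairs, oa, ob)
    assert len(kept) == 10
    assert all(p.gene_a != "ax" for p in kept)


def test_inverted_block_kept():
    """A descending block of 5 is monotone (decreasing) and must survive;
    verified against brute-force enumeration of monotone chains."""
    n = 5
    pairs = [AnchorPair(f"a{i}", f"b{i}", 100.0, 1.0) for i in range(n)]
    oa = {f"a{i}": ("c1", i) for i in range(n)}
    ob = {f"b{i}": ("c1", n - 1 - i) for i in range(n)}
    kept = collinear_chains(pairs, oa, ob, min_anchors=4, max_gap=10)
    assert len(kept) == n

    # brute force: longest monotone chain through each pair
    import itertools
    ranks = [(oa[p.gene_a][1], ob[p.gene_b][1]) for p in pairs]
    best = 0
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            xs = [ranks[i][0] for i in combo]
            ys = [ranks[i][1] for i in combo]
            inc = all(y > x for x, y in zip(ys, ys[1:]))
            dec = all(y < x for x, y in zip(ys, ys[1:]))
            gaps_ok = all(0 < b - a <= 10 for a, b in zip(xs, xs[1:])) and \
                all(0 < abs(b - a) <= 10 for a, b in zip(ys, ys[1:]))
            if (inc or dec) and gaps_ok:
                best = max(best, r)
    assert best == n


def test_cscore_threshold_filters():
    pairs, oa, ob = _diagonal_pairs(10)
    pairs[3].cscore = 0.95
    kept = collinear_chains(pairs, oa, ob, cscore_threshold=0.99)
    assert len(kept) == 9


def test_cscore_threshold_monotone_in_tetrad_count():
    rng = np.random.default_rng(3)
    pairs, oa, ob = _diagonal_pairs(20)
    for p in pairs:
        p.cscore = float(rng.uniform(0.9, 1.0))
    counts = [len(collinear_chains(pairs, oa, ob, cscore_threshold=t))
              for t in (0.9, 0.95, 0.99, 1.0)]
    assert counts == sorted(counts, reverse=True)


def _edge(pairs):
    return [AnchorPair(a, b, 100.0, 1.0) for a, b in pairs]


def test_assemble_consistent_quartet():
    tets = assemble_tetrads(_edge([("ar1", "co1")]), _edge([("ar1", "an1")]),
                            _edge([("co1", "cn1")]), _edge([("an1", "cn1")]))
    assert len(tets) == 1
    assert tets[0].genes == {"Ar": "ar1", "Co": "co1", "An": "an1", "Cn": "cn1"}


def test_assemble_discards_inconsistent_closure():
    tets = assemble_tetrads(_edge([("ar1", "co1")]), _edge([("ar1", "an1")]),
                            _edge([("co1", "cn1")]), _edge([("an1", "cnX")]))
    assert tets == []


def test_assemble_open_quartet_depends_on_flag():
    args = (_edge([("ar1", "co1")]), _edge([("ar1", "an1")]),
            _edge([("co1", "cn1")]), _edge([]))
    assert len(assemble_tetrads(*args)) == 1
    assert assemble_tetrads(*args, require_closed_quartet=True) == []


def test_assemble_enforces_one_to_one():
    # two Ar genes map to the same Cn gene -> both candidate quartets die
    tets = assemble_tetrads(
        _edge([("ar1", "co1"), ("ar2", "co2")]),
        _edge([("ar1", "an1"), ("ar2", "an2")]),
        _edge([("co1", "cn1"), ("co2", "cn1")]),
        _edge([]))
    assert tets == []


def test_tetrads_disjoint_on_simulation(small_ds, small_result):
    seen = set()
    for t in small_result.tetrads:
        for g in t.genes.values():
            assert g not in seen
            seen.add(g)


def test_tetrad_recovery_on_simulation(small_ds, small_result):
    truth = {frozenset(g.values()) for g in small_ds.tetrad_gene_ids.values()}
    found = {frozenset(t.genes.values()) for t in small_result.tetrads}
    assert len(found - truth) == 0  # no false quartets
    assert len(found & truth) >= 0.95 * len(truth)
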