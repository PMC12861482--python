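"""Homoeologous tetrad identification: reciprocal best hits filtered by
collinearity with a cscore criterion.

Orthology between two gene sets is inferred from pairwise similarity of the
gene-anchored sequences (here promoter windows): a shared-k-mer prescreen
nominates a handful of candidate partners per gene, candidates are scored by
banded global alignment (match +1, mismatch -1, gap -2), and a pair is kept
when the two genes are mutually best.  The cscore of a pair is its score over
the best score of either gene (the MCScan convention); pairs inside
collinear chains with cscore >= 0.99 survive, and quartets are assembled from
the four pairwise maps with strict 1:1:1:1 enforcement.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from ._aligner import banded_score, encode

DEFAULT_CSCORE = 0.99
DEFAULT_MIN_ANCHORS = 4
DEFAULT_MAX_GAP = 10
DEFAULT_KMER = 13
# wide enough that cumulative promoter deletions (footprint losses, background
# SVs) keep the true path inside the band
DEFAULT_BAND = 448
DEFAULT_TOP_CANDIDATES = 3


@dataclass
class GeneSeq:
    """A gene's comparable sequence plus its position for collinearity."""

    gene_id: str
    chrom: str
    rank: int  # gene order index along its chromosome
    sequence: str


@dataclass
class AnchorPair:
    gene_a: str
    gene_b: str
    similarity: float
    cscore: float
    ambiguous: bool = False


def _kmer_values(seq: str, k: int) -> np.ndarray:
    """Sorted unique k-mer codes of a sequence (windows containing N
    excluded), via a vectorised rolling encoding."""
    codes = encode(seq).astype(np.int64)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    v = np.zeros(n, dtype=np.int64)
    for j in range(k):
        c = codes[j:j + n]
        v = v * 4 + np.where(c < 4, c, 0)
    bad = np.concatenate(([0], np.cumsum(codes >= 4)))
    valid = (bad[k:] - bad[:-k]) == 0
    return np.unique(v[valid])


def _candidate_pairs(genes_a: list[GeneSeq], genes_b: list[GeneSeq],
                     k: int, top: int) -> set[tuple[int, int]]:
    """Candidate partner pairs by shared-unique-k-mer counts, computed with a
    sorted-array join; for each gene the ``top`` partners are kept, dropping
    partners with less than half the gene's best shared count."""
    import pandas as pd

    vals_a = [_kmer_values(g.sequence, k) for g in genes_a]
    vals_b = [_kmer_values(g.sequence, k) for g in genes_b]
    ka = np.concatenate(vals_a) if vals_a else np.empty(0, np.int64)
    ga = np.repeat(np.arange(len(genes_a)), [len(v) for v in vals_a])
    kb = np.concatenate(vals_b) if vals_b else np.empty(0, np.int64)
    gb = np.repeat(np.arange(len(genes_b)), [len(v) for v in vals_b])
    order = np.argsort(kb, kind="mergesort")
    kbs, gbs = kb[order], gb[order]
    lo = np.searchsorted(kbs, ka, "left")
    hi = np.searchsorted(kbs, ka, "right")
    m = hi - lo
    nz = m > 0
    lo, m, ga_nz = lo[nz], m[nz], ga[nz]
    total = int(m.sum())
    if total == 0:
        return set()
    base = np.repeat(lo, m)
    within = np.arange(total) - np.repeat(np.cumsum(m) - m, m)
    pair_a = np.repeat(ga_nz, m)
    pair_b = gbs[base + within]
    key = pair_a.astype(np.int64) * len(genes_b) + pair_b
    uniq, counts = np.unique(key, return_counts=True)
    df = pd.DataFrame({"a": uniq // len(genes_b), "b": uniq % len(genes_b),
                       "n": counts})
    df = df.sort_values(["n"], ascending=False, kind="mergesort")
    picked: set[tuple[int, int]] = set()
    for col in ("a", "b"):
        sel = df.groupby(col, sort=False).head(top)
        best = df.groupby(col, sort=False)["n"].transform("max")
        keep = df["n"] >= 0.5 * best
        sel = sel[keep.loc[sel.index]]
        picked.update(zip(sel["a"].tolist(), sel["b"].tolist()))
    return picked


def best_hits(genes_a: list[GeneSeq], genes_b: list[GeneSeq],
              k: int = DEFAULT_KMER, band: int = DEFAULT_BAND,
              top_candidates: int = DEFAULT_TOP_CANDIDATES) -> list[AnchorPair]:
    """Reciprocal best hits between two gene sets.

    Candidate partners come from a shared-k-mer prescreen in both directions;
    each candidate pair is scored once by banded global alignment.  For each
    gene the best-scoring partner is retained, pairs are kept iff mutually
    best, and the cscore is score / max(best score of either gene).  Ties are
    broken by lexicographic gene id and flagged ambiguous.
    """
    if not genes_a or not genes_b:
        raise ValueError("both gene sets must be nonempty")
    cand_pairs = _candidate_pairs(genes_a, genes_b, k, top_candidates)

    enc_a = [encode(g.sequence) for g in genes_a]
    enc_b = [encode(g.sequence) for g in genes_b]
    m1, mm, gp = np.float32(1.0), np.float32(-1.0), np.float32(-2.0)
    scores: dict[tuple[int, int], float] = {}
    for ia, ib in sorted(cand_pairs):
        scores[(ia, ib)] = float(banded_score(enc_a[ia], enc_b[ib], band, m1, mm, gp))

    def best_for(side: int) -> tuple[dict[int, int], dict[int, float], set[int]]:
        best_partner: dict[int, int] = {}
        best_score: dict[int, float] = {}
        ambiguous: set[int] = set()
        for (ia, ib), sc in scores.items():
            i, j = (ia, ib) if side == 0 else (ib, ia)
            other = genes_b if side == 0 else genes_a
            if i not in best_score or sc > best_score[i]:
                best_score[i] = sc
                best_partner[i] = j
                ambiguous.discard(i)
            elif sc == best_score[i] and j != best_partner[i]:
                ambiguous.add(i)
                # lexicographic gene-id tiebreak
                if other[j].gene_id < other[best_partner[i]].gene_id:
                    best_partner[i] = j
        return best_partner, best_score, ambiguous

    best_ab, score_a, amb_a = best_for(0)
    best_ba, score_b, amb_b = best_for(1)

    pairs: list[AnchorPair] = []
    for ia, ib in best_ab.items():
        if best_ba.get(ib) != ia:
            continue
        sc = scores[(ia, ib)]
        denom = max(score_a[ia], score_b[ib])
        cscore = sc / denom if denom > 0 else 0.0
        pairs.append(AnchorPair(gene_a=genes_a[ia].gene_id,
                                gene_b=genes_b[ib].gene_id,
                                similarity=sc, cscore=min(cscore, 1.0),
                                ambiguous=(ia in amb_a or ib in amb_b)))
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs


def collinear_chains(pairs: list[AnchorPair],
                     order_a: dict[str, tuple[str, int]],
                     order_b: dict[str, tuple[str, int]],
                     min_anchors: int = DEFAULT_MIN_ANCHORS,
                     max_gap: int = DEFAULT_MAX_GAP,
                     cscore_threshold: float = DEFAULT_CSCORE) -> list[AnchorPair]:
    """Keep pairs belonging to a collinear chain, then apply the cscore cut.

    ``order_a``/``order_b`` map gene ids to (chromosome, rank).  A chain is a
    set of pairs on one chromosome pair, monotone in both genomes (increasing
    or decreasing), with consecutive anchors at most ``max_gap`` gene ranks
    apart in both genomes.  A pair survives when the longest such chain
    through it has >= ``min_anchors`` anchors, found by longest-chain dynamic
    programming in each orientation.
    """
    groups: dict[tuple[str, str], list[AnchorPair]] = defaultdict(list)
    for p in pairs:
        ca, _ = order_a[p.gene_a]
        cb, _ = order_b[p.gene_b]
        groups[(ca, cb)].append(p)

    kept: list[AnchorPair] = []
    for group in groups.values():
        ranked = sorted(group, key=lambda p: (order_a[p.gene_a][1], order_b[p.gene_b][1]))
        ra = np.array([order_a[p.gene_a][1] for p in ranked])
        rb = np.array([order_b[p.gene_b][1] for p in ranked])
        n = len(ranked)
        best_chain = np.ones(n, dtype=int)
        for sign in (1, -1):
            fwd = np.ones(n, dtype=int)
            bwd = np.ones(n, dtype=int)
            for i in range(n):
                for j in range(i - 1, -1, -1):
                    da = ra[i] - ra[j]
                    if da > max_gap:
                        break  # ranked by ra; nothing further back can link
                    db = sign * (rb[i] - rb[j])
                    if 0 < da and 0 < db <= max_gap:
                        fwd[i] = max(fwd[i], fwd[j] + 1)
            for i in range(n - 1, -1, -1):
                for j in range(i + 1, n):
                    da = ra[j] - ra[i]
                    if da > max_gap:
                        break
                    db = sign * (rb[j] - rb[i])
                    if 0 < da and 0 < db <= max_gap:
                        bwd[i] = max(bwd[i], bwd[j] + 1)
            best_chain = np.maximum(best_chain, fwd + bwd - 1)
        for i, p in enumerate(ranked):
            if best_chain[i] >= min_anchors and p.cscore >= cscore_threshold:
                kept.append(p)
    kept.sort(key=lambda p: (p.gene_a, p.gene_b))
    return kept


@dataclass
class Tetrad:
    tetrad_id: str
    genes: dict[str, str]  # genome label -> gene id


def assemble_tetrads(ar_co: list[AnchorPair], ar_an: list[AnchorPair],
                     co_cn: list[AnchorPair], an_cn: list[AnchorPair],
                     require_closed_quartet: bool = False) -> list[Tetrad]:
    """Assemble 1:1:1:1 quartets from the four pairwise syntenic maps.

    A candidate quartet for an Ar gene a is (a, Co partner, An partner,
    Cn partner of the Co partner).  The An-Cn edge, when present, must agree;
    with ``require_closed_quartet`` it must be present.  Any gene occurring in
    more than one candidate quartet discards all its quartets.
    """
    map_ar_co = {p.gene_a: p.gene_b for p in ar_co}
    map_ar_an = {p.gene_a: p.gene_b for p in ar_an}
    map_co_cn = {p.gene_a: p.gene_b for p in co_cn}
    map_an_cn = {p.gene_a: p.gene_b for p in an_cn}

    candidates: list[dict[str, str]] = []
    for a, c in map_ar_co.items():
        n = map_ar_an.get(a)
        m = map_co_cn.get(c)
        if n is None or m is None:
            continue
        closing = map_an_cn.get(n)
        if closing is None:
            if require_closed_quartet:
                continue
        elif closing != m:
            continue
        candidates.append({"Ar": a, "Co": c, "An": n, "Cn": m})

    usage: dict[tuple[str, str], int] = defaultdict(int)
    for q in candidates:
        for genome, gene in q.items():
            usage[(genome, gene)] += 1
    tetrads: list[Tetrad] = []
    for q in candidates:
        if all(usage[(genome, gene)] == 1 for genome, gene in q.items()):
            tetrads.append(Tetrad(tetrad_id="", genes=q))
    tetrads.sort(key=lambda t: t.genes["Ar"])
    for i, t in enumerate(tetrads):
        t.tetrad_id = f"T{i + 1:05d}"
    return tetrads
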