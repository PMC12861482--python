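"""PWM promoter scanning and TFBS conservation scoring.

Motifs are position probability matrices read from JASPAR-style 4-row count
matrices.  A window scores the sum over positions of ln(p_base / 0.25)
(natural-log odds against a uniform background, pseudocount 1e-3); both
strands are scanned and every hit with score > 10 is kept, overlapping hits
included.  Windows containing N are skipped.

A TFBS in a tetraploid promoter counts as conserved when the same motif is
identified in the diploid homoeolog's promoter (presence/absence at motif
identity level); the conservation score of a gene is
conserved hits / total hits, on a 0-1 scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._aligner import encode

DEFAULT_SCORE_THRESHOLD = 10.0
DEFAULT_PSEUDOCOUNT = 1e-3
BACKGROUND = 0.25
_BASES = "ACGT"


@dataclass
class PWM:
    """A motif as a 4xL probability matrix (rows A, C, G, T)."""

    motif_id: str
    matrix: np.ndarray  # shape (4, L), columns sum to 1
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError(f"{self.motif_id}: matrix must be 4xL with L >= 4")
        colsum = self.matrix.sum(axis=0)
        if np.any(np.abs(colsum - 1.0) > 1e-9):
            raise ValueError(f"{self.motif_id}: columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 5) natural-log odds; column 4 (N) is -inf so windows containing
        N can never reach a positive threshold."""
        lo = np.log(self.matrix / BACKGROUND).T  # (L, 4)
        return np.hstack([lo, np.full((self.length, 1), -np.inf)])

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))

    def max_score(self) -> float:
        return float(np.log(self.matrix.max(axis=0) / BACKGROUND).sum())


def normalize_counts(counts: np.ndarray, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    return (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)


def read_jaspar(path: str | Path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWM]:
    """Read a JASPAR-style motif library: '>' header lines followed by four
    rows ``A [ 1 2 3 ]`` ... ``T [ ... ]`` of counts."""
    pwms: list[PWM] = []
    name = None
    rows: dict[str, list[float]] = {}
    def flush():
        if name is None:
            return
        missing = set(_BASES) - set(rows)
        if missing:
            raise ValueError(f"motif {name!r}: missing rows for {sorted(missing)}")
        counts = np.array([rows[b] for b in _BASES], dtype=float)
        pwms.append(PWM(motif_id=name, matrix=normalize_counts(counts, pseudocount),
                        pseudocount=pseudocount))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                rows = {}
            else:
                base = line[0].upper()
                if base not in _BASES:
                    raise ValueError(f"unexpected matrix row: {line!r}")
                nums = line[1:].replace("[", " ").replace("]", " ").split()
                rows[base] = [float(x) for x in nums]
    flush()
    if not pwms:
        raise ValueError(f"{path}: no motifs found")
    return pwms


@dataclass
class MotifHit:
    motif_id: str
    gene_id: str
    offset: int  # window start on the forward promoter coordinates
    strand: str
    log_odds: float

    @property
    def window(self) -> tuple[int, int]:
        return (self.offset, self.offset + self.length)

    length: int = 0


_RC = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def scan_promoter(seq: str, pwm: PWM, gene_id: str = "",
                  threshold: float = DEFAULT_SCORE_THRESHOLD) -> list[MotifHit]:
    """Scan both strands of a promoter with one PWM; keep hits with
    log-odds score strictly above ``threshold``.  Overlapping hits are all
    kept; windows containing N score -inf and are never reported."""
    L = pwm.length
    if len(seq) < L:
        raise ValueError(f"sequence shorter than motif ({len(seq)} < {L})")
    codes = encode(seq)
    lo = pwm.log_odds  # (L, 5)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)  # (W, L)
    idx = np.arange(L)
    fwd = lo[idx[None, :], windows].sum(axis=1)
    # '-' strand: score the reverse complement of each window, i.e. the
    # reverse-complemented matrix applied to forward coordinates
    lo_rc = lo[::-1, _RC]
    rev = lo_rc[idx[None, :], windows].sum(axis=1)
    hits: list[MotifHit] = []
    for strand, scores in (("+", fwd), ("-", rev)):
        for off in np.nonzero(scores > threshold)[0]:
            hits.append(MotifHit(motif_id=pwm.motif_id, gene_id=gene_id,
                                 offset=int(off), strand=strand,
                                 log_odds=float(scores[off]), length=L))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_promoter_all(seq: str, pwms: list[PWM], gene_id: str = "",
                      threshold: float = DEFAULT_SCORE_THRESHOLD) -> list[MotifHit]:
    """Scan one promoter with a whole PWM library.

    Equivalent to concatenating :func:`scan_promoter` over the library
    (asserted by the test suite) but batched by motif length, which is much
    faster when scanning thousands of promoters.
    """
    codes = encode(seq).astype(np.intp)
    by_len: dict[int, list[PWM]] = {}
    for pwm in pwms:
        by_len.setdefault(pwm.length, []).append(pwm)
    hits: list[MotifHit] = []
    for L, group in sorted(by_len.items()):
        if len(seq) < L:
            raise ValueError(f"sequence shorter than motif ({len(seq)} < {L})")
        win = np.lib.stride_tricks.sliding_window_view(codes, L)
        flat = win + np.arange(L) * 5  # (W, L) indices into a (L*5) table
        for strand in ("+", "-"):
            los = []
            for pwm in group:
                lo = pwm.log_odds if strand == "+" else pwm.log_odds[::-1, _RC]
                los.append(lo.reshape(-1))
            table = np.stack(los)  # (k, L*5)
            with np.errstate(invalid="ignore"):
                scores = table[:, flat].sum(axis=2)  # (k, W)
            for ki, pwm in enumerate(group):
                for off in np.nonzero(scores[ki] > threshold)[0]:
                    hits.append(MotifHit(motif_id=pwm.motif_id, gene_id=gene_id,
                                         offset=int(off), strand=strand,
                                         log_odds=float(scores[ki, off]), length=L))
    hits.sort(key=lambda h: (h.motif_id, h.offset, h.strand))
    return hits


def scan_promoter_bruteforce(seq: str, pwm: PWM,
                             threshold: float = DEFAULT_SCORE_THRESHOLD) -> list[MotifHit]:
    """Reference all-window scorer (plain loops); used to validate
    :func:`scan_promoter` on short promoters."""
    from .liftover import reverse_complement

    L = pwm.length
    hits = []
    for off in range(len(seq) - L + 1):
        window = seq[off:off + L]
        if "N" in window:
            continue
        for strand in "+-":
            w = window if strand == "+" else reverse_complement(window)
            score = 0.0
            for k, base in enumerate(w):
                score += float(np.log(pwm.matrix[_BASES.index(base), k] / BACKGROUND))
            if score > threshold:
                hits.append(MotifHit(motif_id=pwm.motif_id, gene_id="",
                                     offset=off, strand=strand,
                                     log_odds=score, length=L))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


@dataclass
class ConservationScore:
    gene_id: str
    n_total: int
    n_conserved: int

    @property
    def cs(self) -> float | None:
        if self.n_total == 0:
            return None
        return self.n_conserved / self.n_total


def tfbs_conservation_score(hits_tetraploid: list[MotifHit],
                            hits_diploid: list[MotifHit],
                            gene_id: str = "",
                            position_matched: bool = False,
                            aln=None, direction: str = "B->A") -> ConservationScore:
    """Conservation score of a tetraploid promoter against its diploid
    homoeolog.

    Default mode counts a tetraploid hit as conserved when its motif is
    identified anywhere in the diploid promoter (motif-identity level).  With
    ``position_matched`` the hit window must additionally lift through the
    promoter alignment ``aln`` (``direction`` names the tetraploid side) onto
    a window overlapping a same-motif diploid hit.
    """
    if not position_matched:
        diploid_motifs = {h.motif_id for h in hits_diploid}
        n_conserved = sum(h.motif_id in diploid_motifs for h in hits_tetraploid)
    else:
        if aln is None:
            raise ValueError("position_matched mode requires a promoter alignment")
        from .liftover import lift_interval

        n_conserved = 0
        for h in hits_tetraploid:
            lifted = lift_interval(h.window, aln, direction=direction)
            if lifted.target is None:
                continue
            ls, le = lifted.target
            if any(d.motif_id == h.motif_id and d.window[0] < le and ls < d.window[1]
                   for d in hits_diploid):
                n_conserved += 1
    return ConservationScore(gene_id=gene_id, n_total=len(hits_tetraploid),
                             n_conserved=n_conserved)


def high_conservation_fraction(scores: list[ConservationScore],
                               cutoff: float = 0.6) -> float:
    """Fraction of genes with CS strictly above ``cutoff`` among genes with a
    defined CS."""
    defined = [s.cs for s in scores if s.cs is not None]
    if not defined:
        raise ValueError("no genes with a defined conservation score")
    return sum(c > cutoff for c in defined) / len(defined)


def tf_target_counts(hits_by_genome: dict[str, list[MotifHit]],
                     genes_by_genome: dict[str, set[str]]) -> "pd.DataFrame":
    """Per-motif counts of tetrad genes with >=1 promoter hit, per genome."""
    import pandas as pd

    motifs = sorted({h.motif_id for hits in hits_by_genome.values() for h in hits})
    if len(motifs) < 2:
        raise ValueError("need at least 2 motifs for target-count comparisons")
    rows = {}
    for genome, hits in hits_by_genome.items():
        tetrad_genes = genes_by_genome[genome]
        per_motif: dict[str, set[str]] = {}
        for h in hits:
            if h.gene_id in tetrad_genes:
                per_motif.setdefault(h.motif_id, set()).add(h.gene_id)
        rows[genome] = [len(per_motif.get(m, ())) for m in motifs]
    return pd.DataFrame(rows, index=pd.Index(motifs, name="motif_id"))


def target_count_comparison(counts: "pd.DataFrame",
                            pairs=(("Ar", "Co"), ("An", "Cn"), ("Ar", "An"), ("Co", "Cn"))):
    """Pearson r and least-squares slope (y on x, with intercept) for each
    genome comparison of per-motif target counts."""
    from scipy import stats as st

    out = []
    for x_label, y_label in pairs:
        x = counts[x_label].to_numpy(dtype=float)
        y = counts[y_label].to_numpy(dtype=float)
        res = st.linregress(x, y)
        out.append({"x": x_label, "y": y_label, "r": float(res.rvalue),
                    "slope": float(res.slope), "intercept": float(res.intercept)})
    return out
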