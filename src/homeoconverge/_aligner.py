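"""Low-level pairwise DNA alignment kernels (numba-jitted).

Two kernels live here:

* a full global affine-gap aligner (Gotoh three-state DP) with a fully
  deterministic traceback, used for promoter-pair alignment, interval
  lift-over and variant calling;
* a banded global aligner with linear gap costs that returns only the score,
  used as the cheap similarity measure for reciprocal-best-hit orthology.

Scoring conventions (fixed, exposed by the callers as configuration):

* affine: match +2, mismatch -3, gap open -5, gap extend -2.  A gap of
  length L costs open + (L-1)*extend, i.e. the first gap base pays the open
  penalty.
* ``N`` never matches anything (scores as a mismatch).
* traceback ties resolve diagonal > gap-in-A > gap-in-B; within a gap state,
  extension is preferred over re-opening.  This makes the aligned-column
  sequence a pure function of the two inputs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = np.float32(-1e30)

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, anything else=4/N)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _affine_fill(a, b, match, mismatch, gap_open, gap_extend):
    """Gotoh fill with rolling score rows.  Returns the final score and the
    three pointer matrices needed for traceback.

    States: M (diagonal), X (gap in B, consumes a), Y (gap in A, consumes b).
    H = max(M, Y, X) with tie order M > Y > X recorded in ptrH.
    """
    n = a.shape[0]
    m = b.shape[0]
    # pointer byte per cell: bits 0-1 = best state (0=M, 1=Y, 2=X),
    # bit 2 = X reached by extension, bit 3 = Y reached by extension
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)

    h_prev = np.empty(m + 1, dtype=np.float32)  # H of row i-1
    x_prev = np.empty(m + 1, dtype=np.float32)  # X of row i-1
    h_cur = np.empty(m + 1, dtype=np.float32)
    x_cur = np.empty(m + 1, dtype=np.float32)

    h_prev[0] = 0.0
    x_prev[0] = NEG_INF
    for j in range(1, m + 1):
        h_prev[j] = gap_open + (j - 1) * gap_extend  # Y run along row 0
        x_prev[j] = NEG_INF
        ptr[0, j] = (1 | 8) if j > 1 else 1
    for i in range(1, n + 1):
        ptr[i, 0] = (2 | 4) if i > 1 else 2

    for i in range(1, n + 1):
        ai = a[i - 1]
        h_cur[0] = gap_open + (i - 1) * gap_extend  # X run along column 0
        x_cur[0] = h_cur[0]
        y_run = NEG_INF  # Y value of current row, previous column
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            mval = h_prev[j - 1] + s

            p = np.uint8(0)
            open_sc = h_prev[j] + gap_open
            ext_sc = x_prev[j] + gap_extend
            if ext_sc >= open_sc:
                xval = ext_sc
                p |= 4
            else:
                xval = open_sc

            open_sc = h_cur[j - 1] + gap_open
            ext_sc = y_run + gap_extend
            if ext_sc >= open_sc:
                yval = ext_sc
                p |= 8
            else:
                yval = open_sc
            y_run = yval

            best = mval
            st = np.uint8(0)
            if yval > best:
                best = yval
                st = np.uint8(1)
            if xval > best:
                best = xval
                st = np.uint8(2)
            ptr[i, j] = p | st
            h_cur[j] = best
            x_cur[j] = xval
        h_prev, h_cur = h_cur, h_prev
        x_prev, x_cur = x_cur, x_prev
    return h_prev[m], ptr


@njit(cache=True)
def _affine_traceback(a, b, ptr):
    n = a.shape[0]
    m = b.shape[0]
    maxlen = n + m
    apos = np.empty(maxlen, dtype=np.int32)
    bpos = np.empty(maxlen, dtype=np.int32)
    k = maxlen
    i = n
    j = m
    state = ptr[n, m] & 3
    while i > 0 or j > 0:
        k -= 1
        if state == 0:  # M: diagonal
            apos[k] = i - 1
            bpos[k] = j - 1
            i -= 1
            j -= 1
            state = ptr[i, j] & 3
        elif state == 1:  # Y: gap in A, consumed b[j-1]
            apos[k] = -1
            bpos[k] = j - 1
            extend = ptr[i, j] & 8
            j -= 1
            state = 1 if extend else ptr[i, j] & 3
        else:  # X: gap in B, consumed a[i-1]
            apos[k] = i - 1
            bpos[k] = -1
            extend = ptr[i, j] & 4
            i -= 1
            state = 2 if extend else ptr[i, j] & 3
    return apos[k:].copy(), bpos[k:].copy()


def global_affine_align(a_codes: np.ndarray, b_codes: np.ndarray,
                        match: float = 2.0, mismatch: float = -3.0,
                        gap_open: float = -5.0, gap_extend: float = -2.0):
    """Global affine-gap alignment of two encoded sequences.

    Returns ``(score, a_pos, b_pos)`` where ``a_pos``/``b_pos`` are int32
    arrays over alignment columns (-1 marks a gap in that sequence).
    """
    if a_codes.shape[0] == 0 or b_codes.shape[0] == 0:
        raise ValueError("cannot align empty sequences")
    score, ptr = _affine_fill(
        a_codes, b_codes, np.float32(match), np.float32(mismatch),
        np.float32(gap_open), np.float32(gap_extend))
    apos, bpos = _affine_traceback(a_codes, b_codes, ptr)
    return float(score), apos, bpos


@njit(cache=True)
def banded_score(a, b, band, match, mismatch, gap):
    """Global alignment score with linear gap costs, restricted to a diagonal
    band of half-width ``band`` around the main diagonal (adjusted for the
    length difference).  Score only; no traceback."""
    n = a.shape[0]
    m = b.shape[0]
    w = band + abs(n - m)
    prev = np.full(m + 1, NEG_INF, dtype=np.float32)
    cur = np.full(m + 1, NEG_INF, dtype=np.float32)
    for j in range(0, min(m, w) + 1):
        prev[j] = j * gap
    for i in range(1, n + 1):
        lo = max(1, i - w)
        hi = min(m, i + w)
        cur[lo - 1] = i * gap if lo == 1 and i <= w else NEG_INF
        if hi < m:
            cur[hi + 1] = NEG_INF  # seal band edge for next row's diagonal read
        ai = a[i - 1]
        for j in range(lo, hi + 1):
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            best = prev[j - 1] + s
            t = prev[j] + gap
            if t > best:
                best = t
            t = cur[j - 1] + gap
            if t > best:
                best = t
            cur[j] = best
        prev, cur = cur, prev
    return prev[m]
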