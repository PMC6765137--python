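"""Low-level sequence comparison kernels.

Sequences are handled as uint8 arrays with A=0, C=1, G=2, T=3 (N=4).
The banded global aligner and the kmer-overlap screens are the hot path of
partitioning, so they are JIT-compiled with numba and cached on disk.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Pointer codes in the traceback matrix. Tie-breaking order when scores are
# equal is diagonal, then up (gap in b), then left (gap in a).
_DIAG = 1
_UP = 2
_LEFT = 3

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGTN"):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (A=0,C=1,G=2,T=3,N=4)."""
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"non-nucleotide character {bad!r} in sequence")
    return arr


def decode(arr: np.ndarray) -> str:
    return _DEC[arr].tobytes().decode("ascii")


@njit(cache=True)
def _nw_banded(a, b, band, match, mismatch, gap):
    """Banded global alignment DP.

    Returns (score, ptr) where ptr is the (len(a)+1, 2*band+1) traceback
    matrix in band coordinates: column j of row i stores the move into cell
    (i, j_global) with j_global = i + (j - band). End gaps are penalized.
    """
    la = len(a)
    lb = len(b)
    width = 2 * band + 1
    NEG = np.float64(-1e18)
    prev = np.full(width, NEG)
    cur = np.full(width, NEG)
    ptr = np.zeros((la + 1, width), dtype=np.uint8)

    # row 0: cell (0, j_global) with j_global = k - band
    for k in range(width):
        jg = k - band
        if 0 <= jg <= lb:
            prev[k] = gap * jg
            if jg > 0:
                ptr[0, k] = _LEFT

    for i in range(1, la + 1):
        for k in range(width):
            cur[k] = NEG
        for k in range(width):
            jg = i + (k - band)
            if jg < 0 or jg > lb:
                continue
            best = NEG
            move = 0
            # diagonal from (i-1, jg-1): same band column k
            if jg >= 1 and prev[k] > NEG / 2:
                s = prev[k] + (match if a[i - 1] == b[jg - 1] else mismatch)
                if s > best:
                    best = s
                    move = _DIAG
            # up from (i-1, jg): band column k+1 in the previous row
            if k + 1 < width and prev[k + 1] > NEG / 2:
                s = prev[k + 1] + gap
                if s > best:
                    best = s
                    move = _UP
            # left from (i, jg-1): band column k-1 in the current row
            if k - 1 >= 0 and cur[k - 1] > NEG / 2:
                s = cur[k - 1] + gap
                if s > best:
                    best = s
                    move = _LEFT
            cur[k] = best
            ptr[i, k] = move
        tmp = prev
        prev = cur
        cur = tmp

    kend = lb - la + band
    score = prev[kend]
    return score, ptr


@njit(cache=True)
def _nw_traceback(ptr, la, lb, band):
    """Recover the alignment path from the banded traceback matrix.

    Returns (a_idx, b_idx) arrays over alignment columns; -1 marks a gap.
    """
    ncol_max = la + lb
    ai = np.empty(ncol_max, dtype=np.int64)
    bi = np.empty(ncol_max, dtype=np.int64)
    i = la
    jg = lb
    n = 0
    while i > 0 or jg > 0:
        k = jg - i + band
        move = ptr[i, k]
        if move == _DIAG:
            i -= 1
            jg -= 1
            ai[n] = i
            bi[n] = jg
        elif move == _UP:
            i -= 1
            ai[n] = i
            bi[n] = -1
        elif move == _LEFT:
            jg -= 1
            ai[n] = -1
            bi[n] = jg
        else:  # dead cell: should not happen for feasible bands
            break
        n += 1
    return ai[:n][::-1].copy(), bi[:n][::-1].copy()


def banded_nw(a: np.ndarray, b: np.ndarray, band: int,
              match: float = 5.0, mismatch: float = -4.0,
              gap: float = -8.0):
    """Banded Needleman-Wunsch global alignment of encoded sequences.

    Returns (score, a_idx, b_idx) or None when the length difference
    exceeds the band (alignment refused; sequences treated as unrelated).
    Equals the unconstrained alignment whenever the optimal path stays
    within ``band`` of the main diagonal.
    """
    if abs(len(a) - len(b)) >= band:
        return None
    score, ptr = _nw_banded(a, b, band, match, mismatch, gap)
    a_idx, b_idx = _nw_traceback(ptr, len(a), len(b), band)
    return float(score), a_idx, b_idx


@njit(cache=True)
def kmer_indices(seq, k):
    """Sequence-ordered array of kmer codes (base-4); N-containing kmers -> -1."""
    n = len(seq) - k + 1
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        code = 0
        ok = True
        for j in range(k):
            c = seq[i + j]
            if c > 3:
                ok = False
                break
            code = code * 4 + c
        out[i] = code if ok else -1
    return out


@njit(cache=True)
def ordered_overlap(ka, kb):
    """Positional matches between two sequence-ordered kmer arrays."""
    n = min(len(ka), len(kb))
    c = 0
    for i in range(n):
        if ka[i] == kb[i] and ka[i] >= 0:
            c += 1
    return c


@njit(cache=True)
def multiset_overlap(sa, sb):
    """Multiset intersection size of two sorted kmer arrays."""
    i = 0
    j = 0
    c = 0
    while i < len(sa) and j < len(sb):
        if sa[i] < sb[j]:
            i += 1
        elif sa[i] > sb[j]:
            j += 1
        else:
            if sa[i] >= 0:
                c += 1
            i += 1
            j += 1
    return c
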