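"""Affine-gap Smith-Waterman kernels (full-matrix and banded), numba-compiled.

Gap cost convention: a gap of length L costs gap_open + gap_extend * L.
The N code (4) never matches anything, including another N.

Op codes emitted by tracebacks: 0 = match, 1 = mismatch,
2 = insertion-in-query (consumes query base only),
3 = deletion-from-query (consumes target base only).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True, nogil=True)
def sw_score(a, b, match, mismatch, gap_open, gap_ext):
    """Best local affine-gap score (score only, O(len(b)) memory)."""
    n, m = a.shape[0], b.shape[0]
    H = np.zeros(m + 1, dtype=np.int64)  # previous row, overwritten in place
    F = np.full(m + 1, NEG, dtype=np.int64)  # vertical gap state per column
    best = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        diag = H[0]  # H[i-1][j-1]
        H[0] = 0
        e = NEG  # horizontal gap state within the row
        for j in range(1, m + 1):
            if ai == b[j - 1] and ai < 4:
                s = diag + match
            else:
                s = diag - mismatch
            f_open = H[j] - gap_open - gap_ext  # H[j] is still row i-1
            f_ext = F[j] - gap_ext
            f = f_ext if f_ext > f_open else f_open
            F[j] = f
            e_open = H[j - 1] - gap_open - gap_ext  # H[j-1] is row i (updated)
            e_ext = e - gap_ext
            e = e_ext if e_ext > e_open else e_open
            diag = H[j]
            h = s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[j] = h
            if h > best:
                best = h
    return best


@njit(cache=True, nogil=True)
def sw_traceback(a, b, match, mismatch, gap_open, gap_ext):
    """Full-matrix local alignment with traceback.

    Returns (score, q_start, q_end, t_start, t_end, ops) where ops is a
    uint8 array of per-column op codes (see module docstring).
    """
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e_ext = E[i, j - 1] - gap_ext
            e_open = H[i, j - 1] - gap_open - gap_ext
            if e_ext > e_open:
                E[i, j] = e_ext
                ebit = 4
            else:
                E[i, j] = e_open
                ebit = 0
            f_ext = F[i - 1, j] - gap_ext
            f_open = H[i - 1, j] - gap_open - gap_ext
            if f_ext > f_open:
                F[i, j] = f_ext
                fbit = 8
            else:
                F[i, j] = f_open
                fbit = 0
            if ai == b[j - 1] and ai < 4:
                s = H[i - 1, j - 1] + match
            else:
                s = H[i - 1, j - 1] - mismatch
            h = 0
            src = 0
            if s > h:
                h = s
                src = 1
            if E[i, j] > h:
                h = E[i, j]
                src = 2
            if F[i, j] > h:
                h = F[i, j]
                src = 3
            H[i, j] = h
            ptr[i, j] = src | ebit | fbit
            if h > best:
                best = h
                bi = i
                bj = j
    ops = np.empty(n + m, dtype=np.uint8)
    k = n + m
    i, j = bi, bj
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if state == 0:
            src = ptr[i, j] & 3
            if src == 0:
                break
            if src == 1:
                k -= 1
                ops[k] = 0 if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else 1
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            k -= 1
            ops[k] = 3
            if ptr[i, j] & 4 == 0:
                state = 0
            j -= 1
        else:
            k -= 1
            ops[k] = 2
            if ptr[i, j] & 8 == 0:
                state = 0
            i -= 1
    return best, i, bi, j, bj, ops[k:]


@njit(cache=True, nogil=True)
def swb_score(a, b, dlo, dhi, match, mismatch, gap_open, gap_ext):
    """Banded local affine score restricted to diagonals dlo <= j - i <= dhi."""
    n, m = a.shape[0], b.shape[0]
    W = dhi - dlo + 1
    Hp = np.zeros(W, dtype=np.int64)
    Ep = np.full(W, NEG, dtype=np.int64)
    Fp = np.full(W, NEG, dtype=np.int64)
    Hc = np.zeros(W, dtype=np.int64)
    Ec = np.full(W, NEG, dtype=np.int64)
    Fc = np.full(W, NEG, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for w in range(W):
            j = i + dlo + w
            if j < 1 or j > m:
                Hc[w] = 0 if 0 <= j <= m else NEG
                Ec[w] = NEG
                Fc[w] = NEG
                continue
            # E from (i, j-1) -> same row, w-1
            if w >= 1:
                e_ext = Ec[w - 1] - gap_ext
                e_open = Hc[w - 1] - gap_open - gap_ext
                e = e_ext if e_ext > e_open else e_open
            else:
                e = NEG
            # F from (i-1, j) -> prev row, w+1
            if w + 1 < W:
                f_ext = Fp[w + 1] - gap_ext
                f_open = Hp[w + 1] - gap_open - gap_ext
                f = f_ext if f_ext > f_open else f_open
            else:
                f = NEG
            # diag from (i-1, j-1) -> prev row, same w
            hd = Hp[w]
            if hd <= NEG // 2:
                s = NEG
            elif ai == b[j - 1] and ai < 4:
                s = hd + match
            else:
                s = hd - mismatch
            h = 0
            if s > h:
                h = s
            if e > h:
                h = e
            if f > h:
                h = f
            Hc[w] = h
            Ec[w] = e
            Fc[w] = f
            if h > best:
                best = h
        Hp, Hc = Hc, Hp
        Ep, Ec = Ec, Ep
        Fp, Fc = Fc, Fp
    return best


@njit(cache=True, nogil=True)
def swb_traceback(a, b, dlo, dhi, match, mismatch, gap_open, gap_ext):
    """Banded local alignment with traceback (same contract as sw_traceback)."""
    n, m = a.shape[0], b.shape[0]
    W = dhi - dlo + 1
    H = np.full((n + 1, W), NEG, dtype=np.int64)
    E = np.full((n + 1, W), NEG, dtype=np.int64)
    F = np.full((n + 1, W), NEG, dtype=np.int64)
    ptr = np.zeros((n + 1, W), dtype=np.uint8)
    for w in range(W):
        j = 0 + dlo + w
        if 0 <= j <= m:
            H[0, w] = 0
    best = 0
    bi = 0
    bw = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for w in range(W):
            j = i + dlo + w
            if j < 0 or j > m:
                continue
            if j == 0:
                H[i, w] = 0
                continue
            if w >= 1:
                e_ext = E[i, w - 1] - gap_ext
                e_open = H[i, w - 1] - gap_open - gap_ext
                if e_ext > e_open:
                    e = e_ext
                    ebit = 4
                else:
                    e = e_open
                    ebit = 0
            else:
                e = NEG
                ebit = 0
            if w + 1 < W:
                f_ext = F[i - 1, w + 1] - gap_ext
                f_open = H[i - 1, w + 1] - gap_open - gap_ext
                if f_ext > f_open:
                    f = f_ext
                    fbit = 8
                else:
                    f = f_open
                    fbit = 0
            else:
                f = NEG
                fbit = 0
            hd = H[i - 1, w]
            if hd <= NEG // 2:
                s = NEG
            elif ai == b[j - 1] and ai < 4:
                s = hd + match
            else:
                s = hd - mismatch
            h = 0
            src = 0
            if s > h:
                h = s
                src = 1
            if e > h:
                h = e
                src = 2
            if f > h:
                h = f
                src = 3
            H[i, w] = h
            E[i, w] = e
            F[i, w] = f
            ptr[i, w] = src | ebit | fbit
            if h > best:
                best = h
                bi = i
                bw = w
    ops = np.empty(n + m, dtype=np.uint8)
    k = n + m
    i, w = bi, bw
    state = 0
    while True:
        j = i + dlo + w
        if state == 0:
            src = ptr[i, w] & 3
            if src == 0:
                break
            if src == 1:
                k -= 1
                ops[k] = 0 if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else 1
                i -= 1
                # diag keeps w
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            k -= 1
            ops[k] = 3
            if ptr[i, w] & 4 == 0:
                state = 0
            w -= 1
        else:
            k -= 1
            ops[k] = 2
            if ptr[i, w] & 8 == 0:
                state = 0
            i -= 1
            w += 1
    j = i + dlo + w
    bj = bi + dlo + bw
    return best, i, bi, j, bj, ops[k:]
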