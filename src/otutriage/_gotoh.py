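"""Affine-gap pairwise alignment kernel (three-state Gotoh DP).

The kernel works on uint8 code arrays and returns the optimal score plus the
alignment path as an array of column operations.  End gaps can be made free
(semi-global / overlap alignment), in which case leading and trailing gap
columns score zero.

Traceback is deterministic: ties prefer substitution columns over gaps in
sequence ``b`` ("deletion", consuming ``a``) over gaps in sequence ``a``
("insertion", consuming ``b``); among equally scoring end cells the
bottom-right corner wins, then later cells on the last row, then later cells
on the last column.

Compiled with numba when available; a pure-Python fallback keeps the module
importable (and correct, just slow) without it.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


NEG = -1.0e30
EPS = 1.0e-6

# column operation codes
OP_DIAG = 0  # a[i] over b[j]
OP_UP = 1  # a[i] over a gap (gap in b)
OP_LEFT = 2  # gap in a over b[j]


@njit(cache=True)
def _align_kernel(a, b, match, mismatch, gap_open, gap_extend, free_ends):
    """Fill + traceback.  Returns (score, ops) with ops ordered left to right.

    Gap cost convention: a gap run of length L costs gap_open +
    (L-1)*gap_extend (both negative).
    """
    n = a.shape[0]
    m = b.shape[0]

    M = np.full((n + 1, m + 1), NEG)  # a[i] aligned to b[j]
    X = np.full((n + 1, m + 1), NEG)  # a[i] aligned to gap
    Y = np.full((n + 1, m + 1), NEG)  # b[j] aligned to gap
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0 if free_ends else gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = 0.0 if free_ends else gap_open + (j - 1) * gap_extend

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > prev:
                prev = Y[i - 1, j - 1]
            M[i, j] = s + prev

            v = M[i - 1, j] + gap_open
            if X[i - 1, j] + gap_extend > v:
                v = X[i - 1, j] + gap_extend
            if Y[i - 1, j] + gap_open > v:
                v = Y[i - 1, j] + gap_open
            X[i, j] = v

            v = M[i, j - 1] + gap_open
            if X[i, j - 1] + gap_open > v:
                v = X[i, j - 1] + gap_open
            if Y[i, j - 1] + gap_extend > v:
                v = Y[i, j - 1] + gap_extend
            Y[i, j] = v

    # pick the traceback start
    bi = n
    bj = m
    bstate = 0
    best = NEG
    if free_ends:
        # preference order: (n, m), then last row right-to-left, then last
        # column bottom-to-top; within a cell M > X > Y.  Strictly-greater
        # comparisons make the first candidate win ties.
        for j in range(m, 0, -1):
            for st in range(3):
                v = M[n, j] if st == 0 else (X[n, j] if st == 1 else Y[n, j])
                if v > best + EPS:
                    best = v
                    bi = n
                    bj = j
                    bstate = st
        for i in range(n, 0, -1):
            for st in range(3):
                v = M[i, m] if st == 0 else (X[i, m] if st == 1 else Y[i, m])
                if v > best + EPS:
                    best = v
                    bi = i
                    bj = m
                    bstate = st
        if n == 0 or m == 0:
            best = 0.0
            bi = n
            bj = m
    else:
        for st in range(3):
            v = M[n, m] if st == 0 else (X[n, m] if st == 1 else Y[n, m])
            if v > best + EPS:
                best = v
                bstate = st
        if not free_ends and n > 0 and m == 0:
            best = X[n, 0]
            bstate = 1
        if not free_ends and n == 0 and m > 0:
            best = Y[0, m]
            bstate = 2

    ops_rev = np.empty(n + m, dtype=np.int8)
    k = 0
    # trailing free end gaps
    for _ in range(m - bj):
        ops_rev[k] = OP_LEFT
        k += 1
    for _ in range(n - bi):
        ops_rev[k] = OP_UP
        k += 1

    i = bi
    j = bj
    st = bstate
    while i > 0 and j > 0:
        if st == 0:
            cur = M[i, j]
            s = match if a[i - 1] == b[j - 1] else mismatch
            ops_rev[k] = OP_DIAG
            k += 1
            if abs(M[i - 1, j - 1] + s - cur) < EPS:
                st = 0
            elif abs(X[i - 1, j - 1] + s - cur) < EPS:
                st = 1
            else:
                st = 2
            i -= 1
            j -= 1
        elif st == 1:
            cur = X[i, j]
            ops_rev[k] = OP_UP
            k += 1
            if abs(M[i - 1, j] + gap_open - cur) < EPS:
                st = 0
            elif abs(X[i - 1, j] + gap_extend - cur) < EPS:
                st = 1
            else:
                st = 2
            i -= 1
        else:
            cur = Y[i, j]
            ops_rev[k] = OP_LEFT
            k += 1
            if abs(M[i, j - 1] + gap_open - cur) < EPS:
                st = 0
            elif abs(X[i, j - 1] + gap_open - cur) < EPS:
                st = 1
            else:
                st = 2
            j -= 1
    # leading gaps down to the origin
    while i > 0:
        ops_rev[k] = OP_UP
        k += 1
        i -= 1
    while j > 0:
        ops_rev[k] = OP_LEFT
        k += 1
        j -= 1

    return best, ops_rev[:k][::-1].copy()
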