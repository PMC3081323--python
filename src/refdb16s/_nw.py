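"""Numba kernel for global alignment with free end gaps (overlap alignment).

Scoring mirrors the megablast-style parameters used throughout the pipeline:
match +1, mismatch -2, gap -2, end gaps free.  Identity is computed from the
traceback, not from the score: matched columns are those where both characters
are identical A/C/G/T; internal gap columns and any column involving a
non-ACGT character count as mismatches; end-gap columns lie outside the
aligned region and are not counted at all.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["encode", "overlap_align"]

# A=0 C=1 G=2 T=3; every other IUPAC character maps to 4 (never a match).
_LUT = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string for the alignment kernel."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


@njit(cache=True)
def _overlap_align_kernel(a, b):  # pragma: no cover - exercised via wrapper
    n = a.shape[0]
    m = b.shape[0]
    S = np.zeros((n + 1, m + 1), dtype=np.int32)
    # pointers: 0 = diagonal, 1 = up (gap in b), 2 = left (gap in a)
    P = np.zeros((n + 1, m + 1), dtype=np.uint8)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1] and ai < 4:
                s = S[i - 1, j - 1] + 1
            else:
                s = S[i - 1, j - 1] - 2
            p = 0
            up = S[i - 1, j] - 2
            if up > s:
                s = up
                p = 1
            left = S[i, j - 1] - 2
            if left > s:
                s = left
                p = 2
            S[i, j] = s
            P[i, j] = p
    # Free trailing end gaps: best cell on the last row or last column.
    # Ties prefer the cell closest to (n, m) along the scan order below.
    bi, bj = n, m
    best = S[n, m]
    for i in range(n, 0, -1):
        if S[i, m] > best:
            best = S[i, m]
            bi, bj = i, m
    for j in range(m, 0, -1):
        if S[n, j] > best:
            best = S[n, j]
            bi, bj = n, j
    # Traceback to the first row/column (free leading end gaps).
    matches = 0
    cols = 0
    i, j = bi, bj
    while i > 0 and j > 0:
        p = P[i, j]
        cols += 1
        if p == 0:
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                matches += 1
            i -= 1
            j -= 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    return matches, cols, best


def overlap_align(a: np.ndarray, b: np.ndarray):
    """Align two encoded sequences; return (matches, aligned_columns, score)."""
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("cannot align an empty sequence")
    m, c, s = _overlap_align_kernel(a, b)
    return int(m), int(c), int(s)
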