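"""Numba dynamic-programming kernels shared by the homology and MSA stages.

A gap of length k costs ``gap_open + k * gap_extend`` (affine; the opening
residue pays both terms). Scores are float64 so the same kernels serve
integer substitution matrices and real-valued profile column scores.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e30


@njit(cache=True)
def sw_score(a, b, S, gap_open, gap_extend):
    """Optimal local-alignment score (score only, rolling rows)."""
    n = a.shape[0]
    m = b.shape[0]
    h_prev = np.zeros(m + 1)
    e_prev = np.full(m + 1, NEG_INF)
    best = 0.0
    for i in range(1, n + 1):
        h_cur = np.zeros(m + 1)
        e_cur = np.full(m + 1, NEG_INF)
        f = NEG_INF
        for j in range(1, m + 1):
            e_cur[j] = max(h_prev[j] - gap_open - gap_extend, e_prev[j] - gap_extend)
            f = max(h_cur[j - 1] - gap_open - gap_extend, f - gap_extend)
            h = h_prev[j - 1] + S[a[i - 1], b[j - 1]]
            val = 0.0
            if h > val:
                val = h
            if e_cur[j] > val:
                val = e_cur[j]
            if f > val:
                val = f
            h_cur[j] = val
            if val > best:
                best = val
        h_prev = h_cur
        e_prev = e_cur
    return best


@njit(cache=True)
def sw_fill(a, b, S, gap_open, gap_extend):
    """Full Smith-Waterman matrices for traceback.

    Returns (H, E, F) where E holds vertical-gap scores (gap in b, 'up'
    moves) and F horizontal-gap scores (gap in a, 'left' moves).
    """
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG_INF)
    F = np.full((n + 1, m + 1), NEG_INF)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i - 1, j] - gap_open - gap_extend, E[i - 1, j] - gap_extend)
            F[i, j] = max(H[i, j - 1] - gap_open - gap_extend, F[i, j - 1] - gap_extend)
            h = H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]
            val = 0.0
            if h > val:
                val = h
            if E[i, j] > val:
                val = E[i, j]
            if F[i, j] > val:
                val = F[i, j]
            H[i, j] = val
    return H, E, F


@njit(cache=True)
def nw_fill(M, gap_open, gap_extend):
    """Global (Needleman-Wunsch) affine DP over a precomputed score matrix.

    ``M[i, j]`` is the score of aligning row-item i against column-item j
    (a substitution-matrix lookup for sequences, a cross-profile expectation
    for profiles). Terminal gaps are penalized. Returns (H, E, F).
    """
    n = M.shape[0]
    m = M.shape[1]
    H = np.full((n + 1, m + 1), NEG_INF)
    E = np.full((n + 1, m + 1), NEG_INF)
    F = np.full((n + 1, m + 1), NEG_INF)
    H[0, 0] = 0.0
    for i in range(1, n + 1):
        E[i, 0] = -gap_open - gap_extend * i
        H[i, 0] = E[i, 0]
    for j in range(1, m + 1):
        F[0, j] = -gap_open - gap_extend * j
        H[0, j] = F[0, j]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i - 1, j] - gap_open - gap_extend, E[i - 1, j] - gap_extend)
            F[i, j] = max(H[i, j - 1] - gap_open - gap_extend, F[i, j - 1] - gap_extend)
            h = H[i - 1, j - 1] + M[i - 1, j - 1]
            val = h
            if E[i, j] > val:
                val = E[i, j]
            if F[i, j] > val:
                val = F[i, j]
            H[i, j] = val
    return H, E, F


def nw_traceback(H, E, F, M, gap_open, gap_extend):
    """Deterministic global traceback: diagonal > up > left on ties.

    Returns a list of (i, j) moves from the alignment start, where i/j is
    the consumed row/column index or -1 for a gap on that side.
    """
    i, j = H.shape[0] - 1, H.shape[1] - 1
    state = "H"
    path: list[tuple[int, int]] = []
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and abs(H[i, j] - (H[i - 1, j - 1] + M[i - 1, j - 1])) < eps:
                path.append((i - 1, j - 1))
                i -= 1
                j -= 1
            elif i > 0 and abs(H[i, j] - E[i, j]) < eps:
                state = "E"
            elif j > 0 and abs(H[i, j] - F[i, j]) < eps:
                state = "F"
            else:  # pragma: no cover - DP recurrence guarantees one branch
                raise RuntimeError("inconsistent traceback state")
        elif state == "E":  # vertical gap: consume a row item
            opened = abs(E[i, j] - (H[i - 1, j] - gap_open - gap_extend)) < eps
            path.append((i - 1, -1))
            i -= 1
            state = "H" if opened else "E"
        else:  # horizontal gap: consume a column item
            opened = abs(F[i, j] - (H[i, j - 1] - gap_open - gap_extend)) < eps
            path.append((-1, j - 1))
            j -= 1
            state = "H" if opened else "F"
    path.reverse()
    return path
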