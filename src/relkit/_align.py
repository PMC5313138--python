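"""Low-level affine-gap dynamic-programming kernels (numba).

All kernels operate on integer-encoded sequences (see :data:`AA_ORDER`).
Gap cost convention: a gap of length k costs ``gap_open + k * gap_extend``.
Traceback tie-break is deterministic: diagonal, then up (gap in target),
then left (gap in query).
"""

from __future__ import annotations

import numpy as np
from numba import njit

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
X_CODE = 20  # unknown residue; mismatches everything

NEG = -1e30


def encode_protein(residues: str) -> np.ndarray:
    """Encode residues as int8 codes; X and '*' map to the X code."""
    out = np.empty(len(residues), dtype=np.int8)
    for i, ch in enumerate(residues.upper()):
        out[i] = AA_INDEX.get(ch, X_CODE)
    return out


def decode_protein(codes: np.ndarray) -> str:
    return "".join(AA_ORDER[c] if c < 20 else "X" for c in codes)


@njit(cache=True)
def _sw_kernel(a, b, sub, gap_open, gap_extend):
    """Local (Smith-Waterman/Gotoh) alignment with affine gaps.

    Returns (score, a_start, a_end, b_start, b_end, n_identical, n_columns).
    Spans are 0-based half-open.  Empty alignment -> score 0 and empty spans.
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (moving along b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (moving along a)
    # pointers: 0 stop, 1 diag, 2 up(F), 3 left(E)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    state_e = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 if E extended
    state_f = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - gap_open - gap_extend
            e_ext = E[i, j - 1] - gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                state_e[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] - gap_open - gap_extend
            f_ext = F[i - 1, j] - gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                state_f[i, j] = 1
            else:
                F[i, j] = f_open
            diag = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            h = 0.0
            p = 0
            if diag >= h:
                h = diag
                p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0, 0, 0
    # traceback
    i, j = bi, bj
    n_id = 0
    n_col = 0
    state = 0  # 0 in H, 2 in F, 3 in E
    while i > 0 and j > 0:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                n_col += 1
                if a[i - 1] == b[j - 1] and a[i - 1] < 20:
                    n_id += 1
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 2:
            n_col += 1
            if state_f[i, j] == 0:
                state = 0
            i -= 1
        else:
            n_col += 1
            if state_e[i, j] == 0:
                state = 0
            j -= 1
    return best, i, bi, j, bj, n_id, n_col


@njit(cache=True)
def _nw_kernel(a, b, sub, gap_open, gap_extend, free_ends):
    """Global (Needleman-Wunsch/Gotoh) alignment with affine gaps.

    With ``free_ends`` terminal gaps cost nothing (overlap semantics).
    Returns (score, n_identical, n_columns, n_terminal_gap_columns,
    aligned_pairs) where aligned_pairs is an (n_col, 2) array of
    (a_index, b_index) with -1 for gaps, in alignment order.
    """
    n, m = len(a), len(b)
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        H[0, j] = 0.0 if free_ends else -gap_open - gap_extend * j
    for i in range(1, n + 1):
        H[i, 0] = 0.0 if free_ends else -gap_open - gap_extend * i
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - gap_open - gap_extend
            e_ext = E[i, j - 1] - gap_extend
            E[i, j] = e_ext if e_ext > e_open else e_open
            f_open = H[i - 1, j] - gap_open - gap_extend
            f_ext = F[i - 1, j] - gap_extend
            F[i, j] = f_ext if f_ext > f_open else f_open
            h = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            if F[i, j] > h:
                h = F[i, j]
            if E[i, j] > h:
                h = E[i, j]
            H[i, j] = h
    bi, bj = n, m
    best = H[n, m]
    if free_ends:
        for j in range(m + 1):
            if H[n, j] > best:
                best = H[n, j]
                bi, bj = n, j
        for i in range(n + 1):
            if H[i, m] > best:
                best = H[i, m]
                bi, bj = i, m
    pairs = np.empty((n + m, 2), dtype=np.int64)
    k = 0
    n_term = 0
    for j in range(m, bj, -1):  # trailing overhang in b
        pairs[k, 0] = -1
        pairs[k, 1] = j - 1
        k += 1
        n_term += 1
    for i in range(n, bi, -1):  # trailing overhang in a
        pairs[k, 0] = i - 1
        pairs[k, 1] = -1
        k += 1
        n_term += 1
    i, j = bi, bj
    n_id = 0
    eps = 1e-9
    state = 0  # 0=H, 2=F, 3=E
    while i > 0 or j > 0:
        if i == 0:
            pairs[k, 0] = -1
            pairs[k, 1] = j - 1
            k += 1
            n_term += 1
            j -= 1
            continue
        if j == 0:
            pairs[k, 0] = i - 1
            pairs[k, 1] = -1
            k += 1
            n_term += 1
            i -= 1
            continue
        if state == 0:
            h = H[i, j]
            diag = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            if abs(h - diag) < eps:
                if a[i - 1] == b[j - 1] and a[i - 1] < 20:
                    n_id += 1
                pairs[k, 0] = i - 1
                pairs[k, 1] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif abs(h - F[i, j]) < eps:
                state = 2
            else:
                state = 3
        elif state == 2:
            pairs[k, 0] = i - 1
            pairs[k, 1] = -1
            k += 1
            f_open = H[i - 1, j] - gap_open - gap_extend
            if abs(F[i, j] - f_open) < eps:
                state = 0
            i -= 1
        else:
            pairs[k, 0] = -1
            pairs[k, 1] = j - 1
            k += 1
            e_open = H[i, j - 1] - gap_open - gap_extend
            if abs(E[i, j] - e_open) < eps:
                state = 0
            j -= 1
    out = pairs[:k][::-1].copy()
    return best, n_id, k, n_term, out


@njit(cache=True)
def _profile_kernel(scores, b, gap_open, gap_extend):
    """Local alignment of a position-specific score matrix against sequence b.

    ``scores`` is (width, n_symbols).  Returns (score, q_start, q_end,
    t_start, t_end, aligned_pairs array as in _nw_kernel).
    """
    n = scores.shape[0]
    m = len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    state_e = np.zeros((n + 1, m + 1), dtype=np.int8)
    state_f = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - gap_open - gap_extend
            e_ext = E[i, j - 1] - gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                state_e[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] - gap_open - gap_extend
            f_ext = F[i - 1, j] - gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                state_f[i, j] = 1
            else:
                F[i, j] = f_open
            diag = H[i - 1, j - 1] + scores[i - 1, b[j - 1]]
            h = 0.0
            p = 0
            if diag >= h:
                h = diag
                p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    pairs = np.empty((n + m, 2), dtype=np.int64)
    k = 0
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0, pairs[:0]
    i, j = bi, bj
    state = 0
    while i > 0 and j > 0:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                pairs[k, 0] = i - 1
                pairs[k, 1] = j - 1
                k += 1
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 2:
            pairs[k, 0] = i - 1
            pairs[k, 1] = -1
            k += 1
            if state_f[i, j] == 0:
                state = 0
            i -= 1
        else:
            pairs[k, 0] = -1
            pairs[k, 1] = j - 1
            k += 1
            if state_e[i, j] == 0:
                state = 0
            j -= 1
    return best, i, bi, j, bj, pairs[:k][::-1].copy()


@njit(cache=True)
def _sw_score_only(a, b, sub, gap_open, gap_extend):
    """Score-only Smith-Waterman (linear memory)."""
    n, m = len(a), len(b)
    Hprev = np.zeros(m + 1)
    Eprev = np.full(m + 1, NEG)
    best = 0.0
    for i in range(1, n + 1):
        Hcur = np.zeros(m + 1)
        Ecur = np.full(m + 1, NEG)
        f = NEG
        for j in range(1, m + 1):
            e_open = Hcur[j - 1] - gap_open - gap_extend
            e_ext = Ecur[j - 1] - gap_extend
            Ecur[j] = e_ext if e_ext > e_open else e_open
            f_open = Hprev[j] - gap_open - gap_extend
            f_ext = f - gap_extend
            f = f_ext if f_ext > f_open else f_open
            diag = Hprev[j - 1] + sub[a[i - 1], b[j - 1]]
            h = 0.0
            if diag > h:
                h = diag
            if f > h:
                h = f
            if Ecur[j] > h:
                h = Ecur[j]
            Hcur[j] = h
            if h > best:
                best = h
        Hprev = Hcur
        Ecur, Eprev = Eprev, Ecur
    return best
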