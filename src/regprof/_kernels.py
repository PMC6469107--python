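"""Numba kernels for affine-gap pairwise alignment (Gotoh three-state DP).

Gap convention: a gap run of length L costs ``gap_open + L * gap_extend``
(the BLAST convention: a length-1 gap costs open + extend).

The local kernel propagates the start coordinate of every optimal path so
that ties between equal-scoring alignments resolve to the smallest
``(q_start, s_start)``, then the smallest ``(q_end, s_end)`` — a fully
deterministic rule.  Pointer matrices record the decisions for traceback.

State codes in pointer matrices:
    H pointers: 0 = stop/local start, 1 = diagonal from H, 2 = from E (gap in
    query), 3 = from F (gap in subject).
    E/F pointers: 0 = gap opened from H, 1 = gap extended.
"""

import numpy as np
from numba import njit

NEG = -1.0e18


@njit(cache=False)
def _lex_lt(a1, a2, b1, b2):
    """(a1, a2) < (b1, b2) lexicographically."""
    return a1 < b1 or (a1 == b1 and a2 < b2)


@njit(cache=False)
def local_dp(q, s, mat, go, ge):
    """Smith-Waterman affine DP. Returns (score, end_i, end_j, Hp, Ep, Fp)."""
    m, n = q.shape[0], s.shape[0]
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    # path start coordinates (1-based) per state
    Hsi = np.zeros((m + 1, n + 1), np.int64)
    Hsj = np.zeros((m + 1, n + 1), np.int64)
    Esi = np.zeros((m + 1, n + 1), np.int64)
    Esj = np.zeros((m + 1, n + 1), np.int64)
    Fsi = np.zeros((m + 1, n + 1), np.int64)
    Fsj = np.zeros((m + 1, n + 1), np.int64)
    Hp = np.zeros((m + 1, n + 1), np.int8)
    Ep = np.zeros((m + 1, n + 1), np.int8)
    Fp = np.zeros((m + 1, n + 1), np.int8)

    big = np.int64(1) << 60
    best = 0.0
    bi = 0
    bj = 0
    bsi = big
    bsj = big
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            # E: alignment ends with a gap in the query (consumes s[j-1])
            e_open = H[i, j - 1] - go - ge
            e_ext = E[i, j - 1] - ge
            if e_open > e_ext or (
                e_open == e_ext
                and not _lex_lt(Esi[i, j - 1], Esj[i, j - 1], Hsi[i, j - 1], Hsj[i, j - 1])
            ):
                E[i, j] = e_open
                Ep[i, j] = 0
                Esi[i, j] = Hsi[i, j - 1]
                Esj[i, j] = Hsj[i, j - 1]
            else:
                E[i, j] = e_ext
                Ep[i, j] = 1
                Esi[i, j] = Esi[i, j - 1]
                Esj[i, j] = Esj[i, j - 1]
            # F: alignment ends with a gap in the subject (consumes q[i-1])
            f_open = H[i - 1, j] - go - ge
            f_ext = F[i - 1, j] - ge
            if f_open > f_ext or (
                f_open == f_ext
                and not _lex_lt(Fsi[i - 1, j], Fsj[i - 1, j], Hsi[i - 1, j], Hsj[i - 1, j])
            ):
                F[i, j] = f_open
                Fp[i, j] = 0
                Fsi[i, j] = Hsi[i - 1, j]
                Fsj[i, j] = Hsj[i - 1, j]
            else:
                F[i, j] = f_ext
                Fp[i, j] = 1
                Fsi[i, j] = Fsi[i - 1, j]
                Fsj[i, j] = Fsj[i - 1, j]
            diag = H[i - 1, j - 1] + mat[q[i - 1], s[j - 1]]
            if H[i - 1, j - 1] > 0.0 or Hp[i - 1, j - 1] != 0:
                dsi = Hsi[i - 1, j - 1]
                dsj = Hsj[i - 1, j - 1]
            else:
                dsi = np.int64(i)
                dsj = np.int64(j)
            # choose among 0, diag, E, F; prefer higher score, then smaller
            # path start, then fixed order diag > E > F
            val = 0.0
            ptr = np.int8(0)
            vsi = np.int64(0)
            vsj = np.int64(0)
            if diag > 0.0:
                val, ptr, vsi, vsj = diag, np.int8(1), dsi, dsj
            if E[i, j] > val or (
                E[i, j] == val and ptr != 0 and _lex_lt(Esi[i, j], Esj[i, j], vsi, vsj)
            ):
                val, ptr, vsi, vsj = E[i, j], np.int8(2), Esi[i, j], Esj[i, j]
            if F[i, j] > val or (
                F[i, j] == val and ptr != 0 and _lex_lt(Fsi[i, j], Fsj[i, j], vsi, vsj)
            ):
                val, ptr, vsi, vsj = F[i, j], np.int8(3), Fsi[i, j], Fsj[i, j]
            if val <= 0.0:
                val, ptr, vsi, vsj = 0.0, np.int8(0), np.int64(0), np.int64(0)
            H[i, j] = val
            Hp[i, j] = ptr
            Hsi[i, j] = vsi
            Hsj[i, j] = vsj
            if val > best or (
                val == best
                and val > 0.0
                and (
                    _lex_lt(vsi, vsj, bsi, bsj)
                    or (vsi == bsi and vsj == bsj and _lex_lt(i, j, bi, bj))
                )
            ):
                best = val
                bi, bj, bsi, bsj = i, j, vsi, vsj
    return best, bi, bj, Hp, Ep, Fp


@njit(cache=False)
def global_dp(q, s, mat, go, ge):
    """Needleman-Wunsch affine DP. Returns (score, Hp, Ep, Fp)."""
    m, n = q.shape[0], s.shape[0]
    H = np.full((m + 1, n + 1), NEG)
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    Hp = np.zeros((m + 1, n + 1), np.int8)
    Ep = np.zeros((m + 1, n + 1), np.int8)
    Fp = np.zeros((m + 1, n + 1), np.int8)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        E[0, j] = -go - ge * j
        H[0, j] = E[0, j]
        Hp[0, j] = 2
        Ep[0, j] = 1 if j > 1 else 0
    for i in range(1, m + 1):
        F[i, 0] = -go - ge * i
        H[i, 0] = F[i, 0]
        Hp[i, 0] = 3
        Fp[i, 0] = 1 if i > 1 else 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - go - ge
            e_ext = E[i, j - 1] - ge
            if e_open >= e_ext:
                E[i, j] = e_open
                Ep[i, j] = 0
            else:
                E[i, j] = e_ext
                Ep[i, j] = 1
            f_open = H[i - 1, j] - go - ge
            f_ext = F[i - 1, j] - ge
            if f_open >= f_ext:
                F[i, j] = f_open
                Fp[i, j] = 0
            else:
                F[i, j] = f_ext
                Fp[i, j] = 1
            diag = H[i - 1, j - 1] + mat[q[i - 1], s[j - 1]]
            val = diag
            ptr = np.int8(1)
            if E[i, j] > val:
                val, ptr = E[i, j], np.int8(2)
            if F[i, j] > val:
                val, ptr = F[i, j], np.int8(3)
            H[i, j] = val
            Hp[i, j] = ptr
    return H[m, n], Hp, Ep, Fp


def traceback(q, s, Hp, Ep, Fp, end_i, end_j, local):
    """Walk pointer matrices back from (end_i, end_j); returns aligned index
    lists where -1 marks a gap, plus the start coordinates (1-based)."""
    ai, aj = [], []
    i, j = end_i, end_j
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 or j > 0:
        if state == 0:
            p = Hp[i, j]
            if local and p == 0:
                break
            if p == 1:
                ai.append(i - 1)
                aj.append(j - 1)
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            elif p == 3:
                state = 2
            else:  # global corner
                break
        elif state == 1:
            ai.append(-1)
            aj.append(j - 1)
            if Ep[i, j] == 0:
                state = 0
            j -= 1
        else:
            ai.append(i - 1)
            aj.append(-1)
            if Fp[i, j] == 0:
                state = 0
            i -= 1
    ai.reverse()
    aj.reverse()
    qs = next((x + 1 for x in ai if x >= 0), 0)
    ss = next((x + 1 for x in aj if x >= 0), 0)
    return ai, aj, qs, ss
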