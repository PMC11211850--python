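"""Affine-gap pairwise alignment used for anchor connection and extension.

A dense Gotoh dynamic program with rows vectorised in numpy.  The insertion
layer's within-row recurrence is folded into a running maximum, which is
score-exact whenever gap-open <= gap-extend (enforced); full traceback is
recovered from the stored layer matrices.

Conventions: the query is transformed *from* the target, so an 'I' consumes
a query character (insertion relative to the target) and a 'D' consumes a
target character.
"""

from __future__ import annotations

import numpy as np

from .scoring import ScoringParams

NEGI = -(2**30)

MAX_CELLS = 8_000_000


def affine_align(query: str, target: str, params: ScoringParams, mode: str = "global"):
    """Align ``query`` against ``target``; returns ``(score, ops)``.

    mode "global": both sequences consumed end to end.
    mode "free_end": the alignment starts at the beginning of both sequences
    but may end anywhere (used for ends-free extension; the empty alignment
    scores 0).
    """
    if params.insert_open > params.insert_extend or params.delete_open > params.delete_extend:
        raise ValueError("affine DP requires gap open <= gap extend")
    m, n = len(query), len(target)
    if (m + 1) * (n + 1) > MAX_CELLS:
        raise ValueError(f"alignment problem too large: {m} x {n}")
    if n == 0:
        if mode == "free_end":
            return 0, ""
        return (0, "") if m == 0 else (
            params.insert_open + (m - 1) * params.insert_extend, "I" * m
        )
    if m == 0:
        if mode == "free_end":
            return 0, ""
        return params.delete_open + (n - 1) * params.delete_extend, "D" * n

    io, ie = params.insert_open, params.insert_extend
    do, de = params.delete_open, params.delete_extend
    q_arr = np.frombuffer(query.encode(), dtype=np.uint8)
    t_arr = np.frombuffer(target.encode(), dtype=np.uint8)

    M = np.full((n + 1, m + 1), NEGI, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEGI, dtype=np.int32)  # 'D' layer
    E = np.full((n + 1, m + 1), NEGI, dtype=np.int32)  # 'I' layer
    M[0, 0] = 0
    E[0, 1:] = io + np.arange(m, dtype=np.int32) * ie
    F[1:, 0] = do + np.arange(n, dtype=np.int32) * de

    js = np.arange(1, m + 1, dtype=np.int32)
    Hp = np.maximum(np.maximum(M[0], F[0]), E[0])
    for i in range(1, n + 1):
        sub = np.where(q_arr == t_arr[i - 1], params.match, params.mismatch).astype(np.int32)
        Mi = M[i]
        Mi[1:] = Hp[:-1] + sub
        Fi = F[i]
        Fi[1:] = np.maximum(Hp[1:] + do, F[i - 1][1:] + de)
        maxMF = np.maximum(Mi, Fi)
        # E[j] = max_{p<j} maxMF[p] + open + (j-1-p)*ext, via a running max of
        # c[p] = maxMF[p] + open - (p+1)*ext so that E[j] = j*ext + cummax(c)[j-1]
        c = maxMF + io - (np.arange(m + 1, dtype=np.int32) + 1) * ie
        cm = np.maximum.accumulate(c)
        Ei = E[i]
        Ei[1:] = np.maximum(Ei[1:], cm[:-1] + js * ie)
        Hp = np.maximum(maxMF, Ei)

    H = np.maximum(np.maximum(M, F), E)
    if mode == "global":
        end = (n, m)
    elif mode == "free_end":
        best = int(H.max())
        if best <= 0:
            return 0, ""
        # tie-break: most query consumed, then least target
        cand = np.argwhere(H == best)
        cand = sorted((int(i), int(j)) for i, j in cand)
        end = max(cand, key=lambda ij: (ij[1], -ij[0]))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    ops = _traceback(M, F, E, q_arr, t_arr, params, end)
    return int(H[end]), ops


def _traceback(M, F, E, q_arr, t_arr, params, end):
    i, j = end
    # layer preference on ties: diagonal, deletion, insertion
    if M[i, j] >= F[i, j] and M[i, j] >= E[i, j]:
        layer = "M"
    elif F[i, j] >= E[i, j]:
        layer = "F"
    else:
        layer = "E"
    io, ie = params.insert_open, params.insert_extend
    de = params.delete_extend
    ops = []
    while i > 0 or j > 0:
        if layer == "M":
            if i == 0 or j == 0:
                break
            ops.append("=" if q_arr[j - 1] == t_arr[i - 1] else "X")
            i, j = i - 1, j - 1
            if M[i, j] >= F[i, j] and M[i, j] >= E[i, j]:
                layer = "M"
            elif F[i, j] >= E[i, j]:
                layer = "F"
            else:
                layer = "E"
        elif layer == "F":
            ops.append("D")
            if i > 1 and F[i, j] == F[i - 1, j] + de:
                i -= 1
            else:
                i -= 1
                layer = "M" if M[i, j] >= E[i, j] else "E"
                if i == 0 and j > 0:
                    layer = "E"
        else:  # E
            ops.append("I")
            if j > 1 and E[i, j] == E[i, j - 1] + ie:
                j -= 1
            else:
                j -= 1
                layer = "M" if M[i, j] >= F[i, j] else "F"
                if j == 0 and i > 0:
                    layer = "F"
        if i == 0 and j == 0:
            break
    return "".join(reversed(ops))
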