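"""Independent reference implementations used as test oracles.

Deliberately naive: plain-python dynamic programs and exhaustive
enumeration, sharing no code with the package's optimised paths.
"""

from mladbg.scoring import NEG_INF

NI = float("-inf")


def gotoh_global(q, t, p):
    """Plain O(nm) affine global alignment score."""
    m, n = len(q), len(t)
    M = [[NI] * (m + 1) for _ in range(n + 1)]
    F = [[NI] * (m + 1) for _ in range(n + 1)]
    E = [[NI] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for j in range(1, m + 1):
        E[0][j] = p.insert_open + (j - 1) * p.insert_extend
    for i in range(1, n + 1):
        F[i][0] = p.delete_open + (i - 1) * p.delete_extend
    for i in range(1, n + 1):
        for j in range(0, m + 1):
            if j >= 1:
                s = p.match if q[j - 1] == t[i - 1] else p.mismatch
                M[i][j] = max(M[i - 1][j - 1], F[i - 1][j - 1], E[i - 1][j - 1]) + s
            F[i][j] = max(
                max(M[i - 1][j], F[i - 1][j], E[i - 1][j]) + p.delete_open,
                F[i - 1][j] + p.delete_extend,
            )
            if j >= 1:
                E[i][j] = max(
                    max(M[i][j - 1], F[i][j - 1], E[i][j - 1]) + p.insert_open,
                    E[i][j - 1] + p.insert_extend,
                )
    return max(M[n][m], F[n][m], E[n][m])


def sw_local(q, t, p):
    """Affine local (Smith-Waterman) alignment score, restartable at 0."""
    m, n = len(q), len(t)
    best = 0
    M = [[0] * (m + 1) for _ in range(n + 1)]
    F = [[NI] * (m + 1) for _ in range(n + 1)]
    E = [[NI] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = p.match if q[j - 1] == t[i - 1] else p.mismatch
            M[i][j] = max(0, max(M[i - 1][j - 1], F[i - 1][j - 1], E[i - 1][j - 1]) + s)
            F[i][j] = max(
                max(M[i - 1][j], F[i - 1][j], E[i - 1][j]) + p.delete_open,
                F[i - 1][j] + p.delete_extend,
            )
            E[i][j] = max(
                max(M[i][j - 1], F[i][j - 1], E[i][j - 1]) + p.insert_open,
                E[i][j - 1] + p.insert_extend,
            )
            if M[i][j] > best:
                best = M[i][j]
    return best


def brute_force_best_chain(anchors, connect, match):
    """Exhaustive maximisation over every ordered anchor subsequence."""
    n = len(anchors)
    overall = None
    for mask in range(1, 1 << n):
        idxs = [i for i in range(n) if mask >> i & 1]
        ok = True
        score = match * anchors[idxs[0]].length
        for a, b in zip(idxs, idxs[1:]):
            A, B = anchors[a], anchors[b]
            if not (A.start < B.start and A.end < B.end):
                ok = False
                break
            c = connect(A, B)
            if c <= NEG_INF:
                ok = False
                break
            score += c
        if ok and (overall is None or score > overall):
            overall = score
    return overall


def naive_seed_matches(query, graph):
    """All (i, node, label) with node's l-suffix equal to query[i:i+l]."""
    l = graph.seed_length
    out = set()
    for i in range(len(query) - l + 1):
        seed = query[i : i + l]
        for node, labels in graph.annotation.items():
            if node.endswith(seed):
                for label in labels:
                    out.add((i, node, label))
    return out


def greedy_disjoint_selection(records, cutoff):
    """Reference greedy disjoint pick by decreasing relative score."""
    ranked = sorted(
        records,
        key=lambda a: (-a.relative_score, a.query_start, a.query_end, a.kind),
    )
    kept = []
    covered = set()
    for a in ranked:
        if a.relative_score < cutoff:
            continue
        cells = set()
        for s, e in a.intervals:
            cells.update(range(s, e))
        if cells & covered:
            continue
        covered |= cells
        kept.append(a)
    return kept
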