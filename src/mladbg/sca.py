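"""Single-label seed-chain-extend alignment (SCA).

Per-label chaining of merged anchors with a walk-cover connect score,
global alignment of the query gap between consecutive anchors against the
spelled cover walk joining them, and ends-free X-drop extension of the
chain's first and last anchors restricted to label-consistent walks.  The
result is the curated pool of label-consistent alignments that multi-label
chaining draws from.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

from .anchoring import derive_anchor_walk, merge_into_mums, seed_and_anchor
from .chaining import chain_forward
from .graph import AnnotatedDBG, WalkCover
from .pairwise import affine_align
from .scoring import NEG_INF, ScoringParams, alignment_score, gap_penalty

logger = logging.getLogger(__name__)

__all__ = ["Alignment", "sca_connect_score", "chain_to_alignment", "align_single_label"]


@dataclass
class Alignment:
    """A label-consistent alignment of a query interval to a graph walk.

    ``ops`` transforms the target spelling into the query substring.  Every
    walk node beyond the first contributes exactly one target character and
    the first node absorbs the remainder (at least the seed length), which
    makes query/target/node bookkeeping linear scans.
    """

    query_start: int
    query_end: int
    label: str
    walk: list
    target: str
    ops: str
    score: int
    query: str = ""
    aln_id: Optional[int] = None
    _prefix: list = field(default_factory=list, repr=False)
    _t_done: list = field(default_factory=list, repr=False)
    _op_idx: list = field(default_factory=list, repr=False)

    def finalise(self, params: ScoringParams) -> "Alignment":
        """Compute prefix scores and query/target/op position maps."""
        prefix = [0]
        t_done = []
        op_idx = []
        cum = 0
        prev = None
        t = 0
        for k, op in enumerate(self.ops):
            if op == "=":
                cum += params.match
            elif op == "X":
                cum += params.mismatch
            elif op == "I":
                cum += params.insert_extend if prev == "I" else params.insert_open
            elif op == "D":
                cum += params.delete_extend if prev == "D" else params.delete_open
            else:
                raise ValueError(f"bad op {op!r}")
            prev = op
            if op in "=XD":
                t += 1
            if op in "=XI":
                prefix.append(cum)
                t_done.append(t)
                op_idx.append(k)
        if len(prefix) - 1 != self.query_end - self.query_start:
            raise ValueError("ops do not span the query interval")
        if t != len(self.target):
            raise ValueError("ops do not span the target")
        if cum != self.score:
            raise ValueError("stored score does not match the edit operations")
        self._prefix = prefix
        self._t_done = t_done
        self._op_idx = op_idx
        return self

    # -- queries -------------------------------------------------------
    def prefix_score(self, p: int) -> int:
        """Score of the alignment truncated at query position p (exclusive)."""
        if not self.query_start <= p <= self.query_end:
            raise ValueError("prefix position outside the aligned interval")
        return self._prefix[p - self.query_start]

    def node_for_target_pos(self, t: int) -> str:
        last = len(self.walk) - 1
        return self.walk[max(0, last - (len(self.target) - 1 - t))]

    def target_slice(self, q0: int, q1: int) -> str:
        """Target substring aligned to query interval [q0, q1)."""
        if not (self.query_start <= q0 <= q1 <= self.query_end):
            raise ValueError("slice outside aligned interval")
        if q0 == q1:
            return ""
        r0, r1 = q0 - self.query_start, q1 - self.query_start
        start = self._t_done[r0 - 1] if r0 > 0 else 0
        return self.target[start : self._t_done[r1 - 1]]

    def exact_match_positions(self, l: int):
        """Query offsets i where q[i:i+l] is an unbroken run of '=' ops."""
        n = self.query_end - self.query_start
        out = []
        for r in range(n - l + 1):
            ok = True
            base = self._op_idx[r]
            for d in range(l):
                if self._op_idx[r + d] != base + d or self.ops[base + d] != "=":
                    ok = False
                    break
            if ok:
                out.append(self.query_start + r)
        return out

    @property
    def length(self) -> int:
        return self.query_end - self.query_start


# ---------------------------------------------------------------------------
# connect score
# ---------------------------------------------------------------------------

def sca_connect_score(a1, a2, cover: WalkCover, params: ScoringParams) -> int:
    """Match score for a2's new characters plus a distance-discrepancy gap.

    The gap penalty compares the query-end difference with the traversal
    distance between the anchor nodes along a shared cover walk; an unknown
    traversal distance forbids the connection.
    """
    if a1.label != a2.label:
        raise ValueError("sca connect requires same-label anchors")
    d = cover.traversal_distance(a1.node, a2.node)
    if d is None:
        return NEG_INF
    qdiff = a2.end - a1.end
    if qdiff > params.max_connect_gap or d > params.max_connect_gap:
        return NEG_INF
    score = params.match * min(a2.length, qdiff)
    g = abs(qdiff - d)
    if g > 0:
        kind = "insertion" if qdiff > d else "deletion"
        score += gap_penalty(g, kind, params)
    return score


# ---------------------------------------------------------------------------
# ends-free extension
# ---------------------------------------------------------------------------

class _ExtState:
    __slots__ = ("sid", "node", "t", "lo", "M", "F", "E", "parent", "char")

    def __init__(self, sid, node, t, lo, M, F, E, parent, char):
        self.sid, self.node, self.t, self.lo = sid, node, t, lo
        self.M, self.F, self.E = M, F, E
        self.parent, self.char = parent, char


def _extension_search(q: str, start_node: str, neighbors, char_of, params: ScoringParams,
                      max_expansions: int = 4000, forced: str = ""):
    """Best-first banded search for the best-scoring extension walk.

    Each step consumes one spelled character; rows are banded around the
    diagonal (X-drop plus slack), and branches whose band maximum falls
    more than X below the global best are abandoned.  ``forced`` spells
    characters that precede any graph step (the unconsumed remainder of the
    boundary node); they add no walk nodes.  Returns the chosen walk's
    nodes and spelling together with the number of query characters
    consumed; the caller re-aligns the chosen pair for exact edit ops.
    """
    if forced:
        real_neighbors, real_char = neighbors, char_of
        boundary_node = start_node

        def neighbors(state):  # noqa: F811
            if isinstance(state, tuple):
                if state[0] == "__root__":
                    return [("__forced__", 0)]
                i = state[1]
                if i + 1 < len(forced):
                    return [("__forced__", i + 1)]
                return real_neighbors(boundary_node)
            return real_neighbors(state)

        def char_of(state):  # noqa: F811
            if isinstance(state, tuple):
                return forced[state[1]]
            return real_char(state)

        start_node = ("__root__",)
    m = len(q)
    xdrop = params.effective_xdrop
    w = xdrop + 4
    match, mism = params.match, params.mismatch
    io, ie = params.insert_open, params.insert_extend
    do, de = params.delete_open, params.delete_extend

    states = []
    # row t=0: only query insertions
    lo = 0
    hi = min(m, w)
    width = hi - lo + 1
    M0 = [NEGI_L] * width
    F0 = [NEGI_L] * width
    E0 = [NEGI_L] * width
    M0[0] = 0
    for j in range(1, width):
        E0[j] = io + (j - 1) * ie
    root = _ExtState(0, start_node, 0, lo, M0, F0, E0, None, "")
    states.append(root)
    best = (0, root, 0)  # score, state, j
    heap = [(0, 0)]  # (-band best, sid)
    expansions = 0
    tmax = m + 2 * w
    while heap and expansions < max_expansions:
        _, sid = heapq.heappop(heap)
        st = states[sid]
        if st.t >= tmax:
            continue
        for nxt in neighbors(st.node):
            expansions += 1
            c = char_of(nxt)
            t2 = st.t + 1
            lo2 = max(0, t2 - w)
            hi2 = min(m, t2 + w)
            if lo2 > hi2:
                continue
            width2 = hi2 - lo2 + 1
            M2 = [NEGI_L] * width2
            F2 = [NEGI_L] * width2
            E2 = [NEGI_L] * width2
            lo1, hi1 = st.lo, st.lo + len(st.M) - 1
            band_best = NEGI_L
            for j in range(lo2, hi2 + 1):
                b2 = j - lo2
                # M: diagonal from (t-1, j-1)
                jp = j - 1
                if lo1 <= jp <= hi1:
                    b1 = jp - lo1
                    h = st.M[b1]
                    if st.F[b1] > h:
                        h = st.F[b1]
                    if st.E[b1] > h:
                        h = st.E[b1]
                    if h > NEGI_L:
                        M2[b2] = h + (match if j >= 1 and q[j - 1] == c else mism)
                # F: vertical from (t-1, j)
                if lo1 <= j <= hi1:
                    b1 = j - lo1
                    h = st.M[b1]
                    if st.F[b1] > h:
                        h = st.F[b1]
                    if st.E[b1] > h:
                        h = st.E[b1]
                    f = st.F[b1] + de
                    g = h + do
                    F2[b2] = f if f > g else g
                # E: horizontal within row
                if b2 >= 1:
                    h = M2[b2 - 1]
                    if F2[b2 - 1] > h:
                        h = F2[b2 - 1]
                    e = E2[b2 - 1] + ie
                    g = h + io
                    E2[b2] = e if e > g else g
                cell = M2[b2]
                if F2[b2] > cell:
                    cell = F2[b2]
                if E2[b2] > cell:
                    cell = E2[b2]
                if cell > band_best:
                    band_best = cell
            if band_best < best[0] - xdrop:
                continue
            sid2 = len(states)
            st2 = _ExtState(sid2, nxt, t2, lo2, M2, F2, E2, sid, c)
            states.append(st2)
            # track global best endpoint (H value, consuming j query chars)
            for j in range(lo2, hi2 + 1):
                b2 = j - lo2
                cell = max(M2[b2], F2[b2], E2[b2])
                if cell > best[0]:
                    best = (cell, st2, j)
            heapq.heappush(heap, (-band_best, sid2))

    score, st, j = best
    if score <= 0 or st.t == 0:
        return [], "", 0
    chars = []
    nodes = []
    cur = st
    while cur.parent is not None:
        chars.append(cur.char)
        if not isinstance(cur.node, tuple):  # skip forced intra-node steps
            nodes.append(cur.node)
        cur = states[cur.parent]
    chars.reverse()
    nodes.reverse()
    return nodes, "".join(chars), j


NEGI_L = -(2**30)


def _extend_forward(graph, label, node, qsuffix, params):
    nodes, spelled, j = _extension_search(
        qsuffix, node,
        lambda v: graph.out_neighbors(v, label),
        lambda v: v[-1],
        params,
    )
    if not spelled:
        return [], "", "", 0
    _, ops = affine_align(qsuffix[:j], spelled, params, "global")
    return nodes, spelled, ops, j


def _extend_backward(graph, label, node, qprefix, params, consumed: int):
    """Extend left of the alignment start.

    ``consumed`` is how many characters of the boundary node's spelling the
    alignment already covers; the remaining k - consumed leading characters
    are spelled before any predecessor step and contribute no new nodes.
    """
    rev = qprefix[::-1]
    forced = node[: len(node) - consumed][::-1]
    nodes, spelled, j = _extension_search(
        rev, node,
        lambda v: graph.in_neighbors(v, label),
        lambda v: v[0],
        params,
        forced=forced,
    )
    if not spelled:
        return [], "", "", 0
    _, ops = affine_align(rev[:j], spelled, params, "global")
    return nodes[::-1], spelled[::-1], ops[::-1], j


# ---------------------------------------------------------------------------
# chain -> alignment
# ---------------------------------------------------------------------------

def chain_to_alignment(chain, graph: AnnotatedDBG, cover: WalkCover, query: str,
                       params: ScoringParams) -> Optional[Alignment]:
    """Extend a single-label chain into a full alignment.

    Consecutive anchors are joined by a global affine alignment of the
    intervening query characters against the spelling of the minimal
    shared cover walk; the chain's outer ends get ends-free extension.  If
    no connecting walk can be realised at alignment time the chain is split
    there and the highest-scoring piece is returned.
    """
    pieces = []
    current = [chain.anchors[0]]
    for prev, cur in zip(chain.anchors, chain.anchors[1:]):
        if cover.walk_slice(prev.node, cur.node) is None:
            logger.warning("chain junction lost its cover walk; splitting chain")
            pieces.append(current)
            current = [cur]
        else:
            current.append(cur)
    pieces.append(current)

    built = []
    for piece in pieces:
        built.append(_assemble_piece(piece, graph, cover, query, params))
    built = [b for b in built if b is not None]
    if not built:
        return None
    return max(built, key=lambda a: (a.score, a.length))


def _assemble_piece(anchors, graph, cover, query, params):
    first = anchors[0]
    label = first.label
    nodes = derive_anchor_walk(first, graph, query)
    ops = "=" * first.length
    target = query[first.start : first.end]
    for prev, cur in zip(anchors, anchors[1:]):
        path = cover.walk_slice(prev.node, cur.node)
        qseg = query[prev.end : cur.end]
        tseg = "".join(n[-1] for n in path[1:])
        _, jops = affine_align(qseg, tseg, params, "global")
        nodes.extend(path[1:])
        ops += jops
        target += tseg
    qs, qe = first.start, anchors[-1].end

    pre_nodes, pre_t, pre_ops, jb = _extend_backward(
        graph, label, nodes[0], query[:qs], params, consumed=params.seed_length
    )
    nodes = pre_nodes + nodes
    target = pre_t + target
    ops = pre_ops + ops
    qs -= jb
    suf_nodes, suf_t, suf_ops, jf = _extend_forward(graph, label, nodes[-1], query[qe:], params)
    nodes = nodes + suf_nodes
    target = target + suf_t
    ops = ops + suf_ops
    qe += jf

    score = alignment_score(ops, params)
    aln = Alignment(qs, qe, label, nodes, target, ops, score, query=query)
    return aln.finalise(params)


# ---------------------------------------------------------------------------
# the single-label pipeline
# ---------------------------------------------------------------------------

def align_single_label(query: str, graph: AnnotatedDBG, params: ScoringParams) -> list:
    """Produce the pool of label-consistent alignments for one query.

    Anchors are merged into MUMs, chained per label, the globally top
    ceil(rho |Q|) chains (with ties) are backtracked, and chains are
    extended in score order, skipping any chain that overlaps a completed
    same-label alignment.
    """
    if params.seed_length != graph.seed_length:
        raise ValueError("params.seed_length differs from the graph's suffix index")
    anchors = merge_into_mums(seed_and_anchor(query, graph), graph, query,
                              unique_in_query=params.mum_unique_in_query)
    if not anchors:
        return []
    by_label: dict = {}
    for a in anchors:
        by_label.setdefault(a.label, []).append(a)

    label_runs = {}
    for label, group in sorted(by_label.items()):
        cover = graph.get_cover(label)
        connect = lambda x, y, c=cover: sca_connect_score(x, y, c, params)  # noqa: E731
        scores = chain_forward(group, connect, len(query), params)
        label_runs[label] = (group, scores, connect)

    max_chains = max(1, math.ceil(params.chain_density * len(query)))
    tips = []
    for label, (group, scores, _) in label_runs.items():
        for i, s in enumerate(scores.scores):
            tips.append((s, label, i))
    tips.sort(key=lambda t: (-t[0], t[1], t[2]))
    if len(tips) > max_chains:
        threshold = tips[max_chains - 1][0]
        tips = [t for t in tips if t[0] >= threshold]

    # backtrack in global score order, anchors single-use within their label
    used: dict = {label: set() for label in label_runs}
    chains = []
    for s, label, idx in tips:
        group, scores, connect = label_runs[label]
        got = _backtrack_one(group, scores, idx, connect, params, used[label])
        if got is not None:
            chains.append(got)
    chains.sort(key=lambda c: (-c.score, c.query_start, min(c.labels)))

    pool = []
    for chain in chains:
        label = next(iter(chain.labels))
        span = (chain.query_start, chain.query_end)
        clash = any(
            a.label == label and min(a.query_end, span[1]) - max(a.query_start, span[0]) > 0
            for a in pool
        )
        if clash:
            continue
        aln = chain_to_alignment(chain, graph, graph.get_cover(label), query, params)
        if aln is not None:
            pool.append(aln)
    for i, a in enumerate(pool):
        a.aln_id = i
    return pool


def _backtrack_one(anchors, scores, tip, connect, params, used):
    """Backtrack a single chain ending at ``tip`` honouring the used set."""
    from .chaining import Chain, rescore_chain, fallback_connect as _fb

    if tip in used:
        return None
    if scores.fallback:
        connect = lambda a, b: _fb(a, b, params)  # noqa: E731
    idx = []
    j = tip
    while j is not None and j not in used:
        idx.append(j)
        j = scores.backpointers[j]
    idx.reverse()
    used.update(idx)
    chain_anchors = [anchors[i] for i in idx]
    return Chain(chain_anchors, rescore_chain(chain_anchors, connect, params))
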