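"""Multi-label chaining (MLC) and stitching into multi-label alignments.

Anchors are re-extracted from the single-label alignment pool, redundant
interior anchors are pruned, and a second chaining pass connects anchors
with a three-case score: (i) extension along the same alignment (a prefix
score difference), (ii) connection of disjoint alignments through a
sentinel gap paying a label-change score, a deletion open, and an
insertion penalty for the skipped query characters, and (iii) connection
of overlapping alignments through an intermediate same-position anchor,
paying a label change plus -- when the hop lands on a different node -- a
node-length-change penalty for traversing through the seed-length suffix
node that proxies the missing k-mers.  Chains are stitched back into
alignments by splicing pool segments; the stitched score reproduces the
chain score exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .anchoring import Anchor
from .chaining import Chain, chain_forward, rescore_chain
from .graph import AnnotatedDBG, longest_common_suffix
from .scoring import (
    NEG_INF,
    LabelChangeScorer,
    LabelStats,
    ScoringParams,
    gap_penalty,
    node_length_change_score,
)
from .sca import align_single_label

logger = logging.getLogger(__name__)

__all__ = [
    "MultiLabelAlignment",
    "MLASegment",
    "MLAJunction",
    "extract_alignment_anchors",
    "mlc_connect_score",
    "MLCScorer",
    "align_multi_label",
    "stitch_chain",
]


@dataclass
class MLASegment:
    aln_id: int
    label: str
    query_start: int
    query_end: int

    @property
    def length(self) -> int:
        return self.query_end - self.query_start


@dataclass
class MLAJunction:
    kind: str  # "extend" | "sentinel" | "overlap"
    score: int
    label_change: int = 0
    node_length_change: int = 0
    gap: int = 0
    same_node: bool = True


@dataclass
class MultiLabelAlignment:
    """Ordered single-label segments joined by scored junction events."""

    segments: list
    junctions: list
    score: int
    target: str  # spelled target with '$' at sentinel junctions
    query: str = ""

    @property
    def query_start(self) -> int:
        return self.segments[0].query_start

    @property
    def query_end(self) -> int:
        return self.segments[-1].query_end

    @property
    def labels(self) -> set:
        return {s.label for s in self.segments}

    def label_coverage(self) -> dict:
        cov: dict = {}
        for s in self.segments:
            cov[s.label] = cov.get(s.label, 0) + s.length
        return cov

    @property
    def covered_length(self) -> int:
        return sum(s.length for s in self.segments)


# ---------------------------------------------------------------------------
# anchor extraction
# ---------------------------------------------------------------------------

def extract_alignment_anchors(pool: list, params: ScoringParams,
                              prune: bool = True) -> list:
    """Seed-length anchors at every exact-match offset of every pool alignment.

    An anchor interior to a run -- the sole anchor at its offset, with
    same-alignment anchors at the previous and next offsets -- carries no
    chaining information (same-alignment connections telescope through
    prefix scores) and is pruned; run heads and tails are kept so chains
    can still enter and leave the run, and any offset shared with another
    alignment is kept because the overlap case hops at matching offsets.
    """
    l = params.seed_length
    raw = []
    for aln in pool:
        if aln.aln_id is None:
            raise ValueError("pool alignments must carry ids")
        last = len(aln.walk) - 1
        tlen = len(aln.target)
        for i in aln.exact_match_positions(l):
            r = i - aln.query_start
            t_end = aln._t_done[r + l - 1] - 1  # target index of q[i+l-1]
            if t_end < l - 1:
                continue  # suffix context incomplete at the walk head
            node = aln.walk[max(0, last - (tlen - 1 - t_end))]
            if node[-l:] != aln.target[t_end - l + 1 : t_end + 1]:
                continue  # window is interior to the walk head, not a suffix
            raw.append(Anchor(i, l, node, aln.label, source=aln.aln_id))

    if not prune:
        raw.sort(key=Anchor.sort_key)
        return raw
    by_pos: dict = {}
    for a in raw:
        by_pos.setdefault(a.start, []).append(a)
    has_at: dict = {}
    for a in raw:
        has_at.setdefault((a.source, a.start), True)
    out = []
    for a in raw:
        sole = len(by_pos[a.start]) == 1
        prev_same = (a.source, a.start - 1) in has_at
        next_same = (a.source, a.start + 1) in has_at
        if sole and prev_same and next_same:
            continue
        out.append(a)
    out.sort(key=Anchor.sort_key)
    return out


# ---------------------------------------------------------------------------
# connection scoring
# ---------------------------------------------------------------------------

class MLCScorer:
    """Three-case connection score over a fixed pool and label statistics."""

    def __init__(self, pool: list, stats: LabelStats, params: ScoringParams,
                 anchors: Optional[list] = None):
        self.pool = {a.aln_id: a for a in pool}
        self.params = params
        self.lc = LabelChangeScorer(stats, params)
        self.by_aln_pos: dict = {}
        for a in anchors or ():
            self.by_aln_pos.setdefault((a.source, a.start), []).append(a)

    def __call__(self, aj: Anchor, aL: Anchor) -> int:
        return self.connect_info(aj, aL).score

    def connect_info(self, aj: Anchor, aL: Anchor) -> MLAJunction:
        if aj.source is None or aL.source is None:
            raise ValueError("multi-label chaining requires pool-sourced anchors")
        p = self.params
        ax, ay = self.pool[aj.source], self.pool[aL.source]
        if aj.source == aL.source:
            s = ay.prefix_score(aL.end) - ay.prefix_score(aj.end)
            return MLAJunction("extend", s)
        if ax.query_start >= ay.query_start:
            return MLAJunction("none", NEG_INF)
        overlap = min(ay.length, ax.query_end - ay.query_start)
        lc = self.lc(aj.label, aL.label)
        if lc <= NEG_INF:
            return MLAJunction("none", NEG_INF)
        if overlap <= 0:
            gap = -overlap
            s = (
                ax.prefix_score(ax.query_end) - ax.prefix_score(aj.end)
                + ay.prefix_score(aL.end)
                + lc
                + p.delete_open
                + (gap_penalty(gap, "insertion", p) if gap >= 1 else 0)
            )
            return MLAJunction(
                "sentinel", s, label_change=lc, gap=gap,
            )
        # overlapping alignments: hop through an intermediate anchor of ay
        if overlap >= p.k - 1:
            return MLAJunction("none", NEG_INF)
        if aj.end - ax.query_start < p.k or ay.query_end - aL.start < p.k:
            return MLAJunction("none", NEG_INF)
        hop = self._intermediate(aj, aL.source)
        if hop is None:
            return MLAJunction("none", NEG_INF)
        differs = hop.node != aj.node
        nc = node_length_change_score(p.k, p.seed_length, p) if differs else 0
        s = (
            ay.prefix_score(aL.end) - ay.prefix_score(aj.end)
            + lc
            + nc
        )
        return MLAJunction(
            "overlap", s, label_change=lc, node_length_change=nc,
            same_node=not differs,
        )

    def _intermediate(self, aj: Anchor, target_aln: int) -> Optional[Anchor]:
        cands = self.by_aln_pos.get((target_aln, aj.start), ())
        if not cands:
            return None
        if not self.params.allow_node_length_change:
            cands = [c for c in cands if c.node == aj.node]
            if not cands:
                return None
        return max(
            cands,
            key=lambda c: (
                c.node == aj.node,
                longest_common_suffix(c.node, aj.node),
                c.node,
            ),
        )


def mlc_connect_score(aj: Anchor, aL: Anchor, pool: list, stats: LabelStats,
                      params: ScoringParams, anchors: Optional[list] = None) -> int:
    """Functional form of the MLC connection score (builds a scorer per call)."""
    if anchors is None:
        anchors = extract_alignment_anchors(pool, params)
    return MLCScorer(pool, stats, params, anchors)(aj, aL)


# ---------------------------------------------------------------------------
# stitching
# ---------------------------------------------------------------------------

def stitch_chain(chain: Chain, pool: list, params: ScoringParams,
                 scorer: MLCScorer) -> MultiLabelAlignment:
    """Splice pool segments along a multi-label chain.

    The stitched total is recomputed from segment prefix-score differences
    plus junction scores and must equal the chain score exactly; a mismatch
    is an internal invariant breach and raises.
    """
    by_id = {a.aln_id: a for a in pool}
    first = chain.anchors[0]
    segments = [MLASegment(first.source, first.label, first.start, first.end)]
    junctions = []
    for prev, cur in zip(chain.anchors, chain.anchors[1:]):
        info = scorer.connect_info(prev, cur)
        if info.score <= NEG_INF:
            raise ValueError("chain contains a forbidden junction")
        seg = segments[-1]
        if info.kind == "extend":
            seg.query_end = cur.end
        elif info.kind == "sentinel":
            seg.query_end = by_id[seg.aln_id].query_end
            ay = by_id[cur.source]
            segments.append(MLASegment(cur.source, cur.label, ay.query_start, cur.end))
            junctions.append(info)
        elif info.kind == "overlap":
            seg.query_end = prev.end
            segments.append(MLASegment(cur.source, cur.label, prev.end, cur.end))
            junctions.append(info)
        else:  # pragma: no cover - chain built from finite scores only
            raise ValueError("unscorable junction in chain")

    total = 0
    for si, seg in enumerate(segments):
        a = by_id[seg.aln_id]
        if si == 0:
            # the chain opens with a bare seed match: score it as such rather
            # than by prefix difference, which would charge any deletion ops
            # sitting between the previous query position and the seed
            total += params.match * first.length + (
                a.prefix_score(seg.query_end) - a.prefix_score(first.end)
            )
        else:
            total += a.prefix_score(seg.query_end) - a.prefix_score(seg.query_start)
    total += sum(_junction_contribution(j, params) for j in junctions)
    if total != chain.score:
        raise ValueError(
            f"stitched score {total} != chain score {chain.score}: "
            "segment slicing inconsistency"
        )

    parts = []
    for idx, seg in enumerate(segments):
        a = by_id[seg.aln_id]
        if idx > 0 and junctions[idx - 1].kind == "sentinel":
            parts.append("$")
        parts.append(a.target_slice(seg.query_start, seg.query_end))
    return MultiLabelAlignment(segments, junctions, total, "".join(parts))


def _junction_contribution(j: MLAJunction, params: ScoringParams) -> int:
    if j.kind == "sentinel":
        return (
            j.label_change + params.delete_open
            + (gap_penalty(j.gap, "insertion", params) if j.gap >= 1 else 0)
        )
    return j.label_change + j.node_length_change


# ---------------------------------------------------------------------------
# the multi-label pipeline
# ---------------------------------------------------------------------------

def align_multi_label(query: str, graph: AnnotatedDBG, params: ScoringParams,
                      pool: Optional[list] = None,
                      stats: Optional[LabelStats] = None) -> list:
    """Chain pool anchors with multi-label scoring and stitch the winners.

    One chain is backtracked per distinct terminal-anchor label, anchors
    remaining globally single-use.
    """
    if pool is None:
        pool = align_single_label(query, graph, params)
    if not pool:
        return []
    if stats is None:
        stats = graph.label_stats()
    anchors = extract_alignment_anchors(pool, params)
    if not anchors:
        return []
    scorer = MLCScorer(pool, stats, params, anchors)
    scores = chain_forward(anchors, scorer, len(query), params)

    order = sorted(range(len(anchors)), key=lambda i: (-scores.scores[i], i))
    used: set = set()
    done_labels: set = set()
    out = []
    for tip in order:
        label = anchors[tip].label
        if label in done_labels or tip in used:
            continue
        idx = []
        j = tip
        while j is not None and j not in used:
            idx.append(j)
            j = scores.backpointers[j]
        idx.reverse()
        used.update(idx)
        chain_anchors = [anchors[i] for i in idx]
        done_labels.add(label)
        # always (re-)score through the model; a fallback pass may have
        # chained anchors the model forbids, in which case drop the chain
        chain = Chain(chain_anchors, rescore_chain(chain_anchors, scorer, params))
        if chain.score <= NEG_INF // 2:
            continue
        out.append(stitch_chain(chain, pool, params, scorer))
    out.sort(key=lambda m: (-m.score, m.query_start))
    return out
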