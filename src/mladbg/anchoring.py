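"""Seed extraction, anchoring, and merging into maximal unique matches.

An anchor ties an exact l-mer match of the query to a (node, label) pair
via the graph's suffix index.  Runs of same-label anchors at consecutive
query offsets whose nodes are graph-adjacent are merged into longer
matches; merging only follows links that are unambiguous on the graph side
(at most one candidate in either direction within the label), so merged
matches are maximal and unique per (label, query interval).  Anchors of
length > l store only the terminal node; the underlying walk is
re-derivable on demand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .graph import DNA, AnnotatedDBG

logger = logging.getLogger(__name__)

__all__ = ["Anchor", "seed_and_anchor", "merge_into_mums", "derive_anchor_walk"]


@dataclass(frozen=True)
class Anchor:
    """Exact match of query[start : start+length] under one label.

    ``node`` is the last node of the (implicit) anchor walk.  ``source`` is
    set when the anchor was extracted from a pool alignment (the MLC stage)
    and holds that alignment's pool id.
    """

    start: int          # 0-based query offset
    length: int
    node: str
    label: str
    source: Optional[int] = None

    @property
    def end(self) -> int:
        return self.start + self.length

    def sort_key(self):
        return (self.end, self.start, self.label, self.node)


def seed_and_anchor(query: str, graph: AnnotatedDBG) -> list:
    """One anchor per (l-mer occurrence, matching node, label) triple.

    Output is sorted by increasing end position, the input contract of the
    chaining forward pass.
    """
    l = graph.seed_length
    if len(query) < l:
        logger.warning("query shorter than seed length %d; no anchors", l)
        return []
    anchors = []
    for i in range(len(query) - l + 1):
        for node, label in graph.suffix_lookup(query[i : i + l]):
            anchors.append(Anchor(i, l, node, label))
    anchors.sort(key=Anchor.sort_key)
    return anchors


def merge_into_mums(anchors: list, graph: AnnotatedDBG, query: str,
                    unique_in_query: bool = False) -> list:
    """Merge unambiguous runs of adjacent same-label anchors.

    A link from anchor a at offset i to anchor b at offset i+1 requires the
    implicit-edge relation between their nodes.  Only links that are unique
    in both directions (one candidate successor and one candidate
    predecessor within the label) are followed, keeping merged matches
    unique in the label's subgraph; ambiguous runs stay unmerged.  With
    ``unique_in_query`` the offsets involved must additionally carry a
    single anchor for the label.
    """
    by_label: dict = {}
    for a in anchors:
        by_label.setdefault(a.label, []).append(a)
    merged = []
    for label, group in by_label.items():
        by_pos: dict = {}
        for a in group:
            by_pos.setdefault(a.start, []).append(a)
        succ: dict = {}
        pred: dict = {}
        for a in group:
            for b in by_pos.get(a.start + 1, ()):
                if a.node[1:] == b.node[:-1]:
                    succ.setdefault(a, []).append(b)
                    pred.setdefault(b, []).append(a)

        def linked(a, b):
            if len(succ.get(a, ())) != 1 or len(pred.get(b, ())) != 1:
                return False
            if unique_in_query and (
                len(by_pos[a.start]) != 1 or len(by_pos[b.start]) != 1
            ):
                return False
            return True

        consumed = set()
        for a in sorted(group, key=Anchor.sort_key):
            if a in consumed:
                continue
            ps = pred.get(a, ())
            if len(ps) == 1 and linked(ps[0], a):
                continue  # interior or terminal of a run; handled from its head
            run = [a]
            cur = a
            while True:
                ss = succ.get(cur, ())
                if len(ss) == 1 and linked(cur, ss[0]):
                    cur = ss[0]
                    run.append(cur)
                else:
                    break
            consumed.update(run)
            merged.append(
                Anchor(a.start, a.length + len(run) - 1, run[-1].node, label)
            )
    merged.sort(key=Anchor.sort_key)
    return merged


def derive_anchor_walk(anchor: Anchor, graph: AnnotatedDBG, query: str) -> list:
    """Reconstruct the node walk behind a (possibly merged) anchor.

    Steps backwards from the terminal node; each predecessor within the
    label is unique for merged MUMs, but any remaining ambiguity is broken
    lexicographically.
    """
    l = graph.seed_length
    nodes = [anchor.node]
    v = anchor.node
    pool = graph.label_nodes[anchor.label]
    for _ in range(anchor.length - l):
        cands = sorted(c + v[:-1] for c in DNA if c + v[:-1] in pool)
        if not cands:
            raise ValueError("anchor walk is not re-derivable; graph changed?")
        v = cands[0]
        nodes.append(v)
    nodes.reverse()
    return nodes
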