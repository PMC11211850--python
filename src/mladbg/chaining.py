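"""Local colinear chaining with a cost-converted termination rule.

The forward pass is parametric in the ``connect`` callback so the
single-label aligner and the multi-label chainer share it.  Banded passes
repeat with geometrically growing bandwidth until the cost equivalent of
the best score found, ceil(2(|Q| - s_best/match)), is covered by the band
last used; a chain that good cannot hide a gap wider than its own cost, so
nothing outside the explored band can improve on it.  When there are more
anchors than query characters, a single fixed-band pass with plain affine
gap costs (graph distances ignored) is used instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Optional

from .anchoring import Anchor
from .scoring import NEG_INF, ScoringParams, gap_penalty

__all__ = ["ChainScores", "Chain", "chain_forward", "backtrack_chains", "fallback_connect"]


@dataclass
class ChainScores:
    """Per-anchor best chain scores and backpointers from a forward pass."""

    scores: list
    backpointers: list
    bandwidth: int          # final band used
    fallback: bool = False
    passes: int = 1


@dataclass
class Chain:
    anchors: list
    score: int
    labels: set = field(default_factory=set)

    def __post_init__(self):
        if not self.labels:
            self.labels = {a.label for a in self.anchors}

    @property
    def query_start(self) -> int:
        return self.anchors[0].start

    @property
    def query_end(self) -> int:
        return self.anchors[-1].end


def fallback_connect(a1: Anchor, a2: Anchor, params: ScoringParams) -> int:
    """Minimap2-style connect: match new characters, penalise the query gap."""
    new = min(a2.length, a2.end - a1.end)
    gap = a2.start - a1.end
    score = params.match * new
    if gap > 0:
        score += gap_penalty(gap, "insertion", params)
    return score


def _banded_pass(anchors, ends, connect, band, scores, bp):
    n = len(anchors)
    F = 0
    for L in range(n):
        aL = anchors[L]
        while F < L and ends[L] - ends[F] > band:
            F += 1
        best_s = scores[L]
        best_j = bp[L]
        best_gap = None if best_j is None else ends[L] - ends[best_j]
        for j in range(F, L):
            aj = anchors[j]
            if aj.start >= aL.start or ends[j] >= ends[L]:
                continue
            c = connect(aj, aL)
            if c <= NEG_INF:
                continue
            s = scores[j] + c
            gap = ends[L] - ends[j]
            if s > best_s or (
                s == best_s
                and best_j is not None
                and (gap, j) < (best_gap, best_j)
            ):
                best_s, best_j, best_gap = s, j, gap
        scores[L] = best_s
        bp[L] = best_j


def chain_forward(
    anchors: list,
    connect: Callable[[Anchor, Anchor], int],
    query_length: int,
    params: ScoringParams,
) -> ChainScores:
    """Forward pass of the local chaining DP.

    Anchors must be sorted by non-decreasing end position.  Scores are
    initialised to ``match * length`` (a single-anchor chain is always
    available) and only ever improve across passes.
    """
    n = len(anchors)
    ends = [a.end for a in anchors]
    if any(e2 < e1 for e1, e2 in zip(ends, ends[1:])):
        raise ValueError("anchors must be sorted by end position")
    scores = [params.match * a.length for a in anchors]
    bp: list = [None] * n
    if n == 0:
        return ChainScores(scores, bp, params.bandwidth)

    if n > query_length:
        _banded_pass(anchors, ends, lambda a, b: fallback_connect(a, b, params),
                     params.bandwidth, scores, bp)
        return ChainScores(scores, bp, params.bandwidth, fallback=True)

    span = ends[-1] - ends[0]
    b = params.bandwidth
    passes = 0
    while True:
        _banded_pass(anchors, ends, connect, b, scores, bp)
        passes += 1
        b_last = b
        b = int(math.ceil(b * params.bandwidth_growth))
        s_best = max(scores)
        # cost conversion in rational arithmetic to avoid float drift
        c_best = math.ceil(2 * (query_length - Fraction(s_best, params.match)))
        if c_best <= b_last or b_last >= span:
            break
    return ChainScores(scores, bp, b_last, passes=passes)


def rescore_chain(chain_anchors: list, connect, params: ScoringParams) -> int:
    total = params.match * chain_anchors[0].length
    for a, b in zip(chain_anchors, chain_anchors[1:]):
        total += connect(a, b)
    return total


def backtrack_chains(
    anchors: list,
    scores: ChainScores,
    max_chains: int,
    connect: Callable[[Anchor, Anchor], int],
    params: ScoringParams,
    used: Optional[set] = None,
) -> list:
    """Reconstruct chains in decreasing score order, one chain per anchor.

    All chains tied at the score cut-off are retained.  A backtrace stops
    as soon as it reaches an already-chained anchor; truncated chains are
    re-scored through ``connect``.  ``used`` may be shared across calls to
    keep anchor use global.
    """
    n = len(anchors)
    if n == 0:
        return []
    if scores.fallback:
        connect = lambda a, b: fallback_connect(a, b, params)  # noqa: E731
    order = sorted(range(n), key=lambda i: (-scores.scores[i], i))
    if 1 <= max_chains < len(order):
        threshold = scores.scores[order[max_chains - 1]]
        order = [i for i in order if scores.scores[i] >= threshold]
    used = set() if used is None else used
    chains = []
    for tip in order:
        if tip in used:
            continue
        idx = []
        j = tip
        while j is not None and j not in used:
            idx.append(j)
            j = scores.backpointers[j]
        idx.reverse()
        used.update(idx)
        chain_anchors = [anchors[i] for i in idx]
        for a, b in zip(idx, idx[1:]):
            if not (anchors[a].start < anchors[b].start and anchors[a].end < anchors[b].end):
                raise ValueError("inconsistent backpointers: colinearity violated")
        chains.append(Chain(chain_anchors, rescore_chain(chain_anchors, connect, params)))
    chains.sort(key=lambda c: (-c.score, c.query_start))
    return chains
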