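"""Scoring model for multi-label alignment.

Holds the classical edit/affine-gap scores, the label-change score (the
floored, scaled log conditional probability that a node observed under the
destination label is also present in the source sample), and the
node-length-change penalty used when a shorter-suffix node stands in for a
missing k-mer during variable-order traversal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Optional

__all__ = [
    "NEG_INF",
    "ScoringParams",
    "LabelStats",
    "gap_penalty",
    "conditional_label_prob",
    "label_change_score",
    "node_length_change_score",
    "alignment_score",
    "LabelChangeScorer",
]

# Finite stand-in for -inf: one forbidden event must outweigh any achievable
# chain score, but sums of a few sentinels must never wrap or poison floats.
NEG_INF = -(2**30)


@dataclass
class ScoringParams:
    """All tunable constants of the aligner.

    Defaults are the standard configuration: unit match/mismatch/gap scores,
    label-change scaling equal to the match score, node-length-change unit
    penalty equal to the gap-extension score, chain density 0.01, initial
    chaining bandwidth 400 with growth factor 4, seed length 19 on an
    order-31 graph, and a 0.05 sketch error.
    """

    match: int = 1
    mismatch: int = -1
    insert_open: int = -1
    insert_extend: int = -1
    delete_open: int = -1
    delete_extend: int = -1
    lambda_lc: float = 1.0
    delta_j: int = -1
    bandwidth: int = 400
    bandwidth_growth: float = 4.0
    chain_density: float = 0.01
    seed_length: int = 19
    k: int = 31
    hll_error: float = 0.05
    sketch_backend: str = "hll"
    xdrop: Optional[int] = None  # None -> 2*(|insert_open| + 5*|insert_extend|)
    allow_node_length_change: bool = True
    mum_unique_in_query: bool = False
    max_connect_gap: int = 2000

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be positive")
        for name in ("mismatch", "insert_open", "insert_extend", "delete_open", "delete_extend"):
            if getattr(self, name) >= 0:
                raise ValueError(f"{name} must be negative")
        if self.delta_j >= 0:
            raise ValueError("delta_j must be negative")
        if self.bandwidth_growth <= 1:
            raise ValueError("bandwidth_growth must exceed 1")
        if not 0 < self.chain_density <= 1:
            raise ValueError("chain_density must be in (0, 1]")
        if not 1 <= self.seed_length <= self.k:
            raise ValueError("seed_length must satisfy 1 <= l <= k")
        if self.bandwidth < 1:
            raise ValueError("bandwidth must be >= 1")
        if self.sketch_backend not in ("hll", "exact"):
            raise ValueError("sketch_backend must be 'hll' or 'exact'")

    @property
    def effective_xdrop(self) -> int:
        if self.xdrop is not None:
            return self.xdrop
        return 2 * (abs(self.insert_open) + 5 * abs(self.insert_extend))

    def with_(self, **kw) -> "ScoringParams":
        return replace(self, **kw)

    # -- key=value config files ---------------------------------------
    @classmethod
    def from_config(cls, path, **overrides) -> "ScoringParams":
        """Read ``key=value`` lines (# comments allowed); overrides win."""
        known = {f.name: f.type for f in fields(cls)}
        kw = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, val = (part.strip() for part in line.split("=", 1))
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
                kw[key] = _coerce(val)
        kw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kw)


def _coerce(val: str):
    low = val.lower()
    if low in ("true", "false"):
        return low == "true"
    if low in ("none", ""):
        return None
    try:
        return int(val)
    except ValueError:
        try:
            return float(val)
        except ValueError:
            return val


@dataclass
class LabelStats:
    """Per-label cardinalities and sketches backing label-change scores."""

    sizes: dict
    sketches: dict
    total: int
    exact_sets: Optional[dict] = None

    def __post_init__(self):
        if any(s <= 0 for s in self.sizes.values()):
            raise ValueError("label cardinalities must be positive")
        if any(s > self.total for s in self.sizes.values()):
            raise ValueError("label cardinality exceeds total node count")

    def check_label(self, label: str) -> None:
        if label not in self.sizes:
            raise KeyError(f"unknown label {label!r}")


def gap_penalty(gap_length: int, kind: str, params: ScoringParams) -> int:
    """Affine gap penalty: open + (len-1) * extend, always <= 0."""
    if gap_length < 1:
        raise ValueError("gap_length must be >= 1")
    if kind == "insertion":
        return params.insert_open + (gap_length - 1) * params.insert_extend
    if kind == "deletion":
        return params.delete_open + (gap_length - 1) * params.delete_extend
    raise ValueError(f"unknown gap kind {kind!r}")


def conditional_label_prob(stats: LabelStats, l1: str, l2: str, backend: str = "exact") -> float:
    """Pr(l1 | l2): probability a node of label l2 also carries label l1.

    The exact backend uses stored node sets; the sketch backend estimates
    the intersection by inclusion-exclusion from the union sketch and the
    exact per-label cardinalities, clipped into [0, 1].
    """
    stats.check_label(l1)
    stats.check_label(l2)
    n1, n2 = stats.sizes[l1], stats.sizes[l2]
    if n2 <= 0:
        raise ValueError(f"label {l2!r} has no nodes")
    if backend == "exact":
        if stats.exact_sets is None:
            raise ValueError("exact backend requested but exact sets not stored")
        inter = len(stats.exact_sets[l1] & stats.exact_sets[l2])
        return inter / n2
    if backend == "sketch":
        union = stats.sketches[l1].union(stats.sketches[l2]).cardinality()
        return max(0.0, min(1.0, (n1 + n2 - union) / n2))
    raise ValueError(f"unknown backend {backend!r}")


def label_change_score(
    stats: LabelStats, l1: str, l2: str, params: ScoringParams, backend: Optional[str] = None
) -> int:
    """Score of the label change l1 -> l2; 0 for l1 == l2, else <= 0.

    The scaled log2 conditional probability is floored to an integer so the
    penalty stays conservative under integer chain arithmetic.  A zero
    probability estimate maps to the finite ``NEG_INF`` sentinel.
    """
    stats.check_label(l1)
    stats.check_label(l2)
    if l1 == l2:
        return 0
    if backend is None:
        backend = "exact" if params.sketch_backend == "exact" else "sketch"
    p = conditional_label_prob(stats, l1, l2, backend=backend)
    if p <= 0.0:
        return NEG_INF
    return min(0, math.floor(params.lambda_lc * math.log2(p)))


def node_length_change_score(l1: int, l2: int, params: ScoringParams) -> int:
    """Penalty for a traversal changing the node length from l1 to l2.

    Free when staying at full order k or growing by one; (k - l2) * delta_j
    when dropping from a full-order node to a shorter suffix; forbidden
    (sentinel) otherwise.
    """
    k = params.k
    if not (1 <= l1 <= k and 1 <= l2 <= k):
        raise ValueError("node lengths must lie in [1, k]")
    if (l1 == l2 == k) or (l1 + 1 == l2):
        return 0
    if l1 == k and l2 < k:
        return (k - l2) * params.delta_j
    return NEG_INF


def alignment_score(edit_ops: str, params: ScoringParams) -> int:
    """Score an edit-operation string over {=, X, I, D} with affine runs.

    The first operation of each gap run pays the open score, subsequent ones
    the extension score.
    """
    score = 0
    prev = None
    for op in edit_ops:
        if op == "=":
            score += params.match
        elif op == "X":
            score += params.mismatch
        elif op == "I":
            score += params.insert_extend if prev == "I" else params.insert_open
        elif op == "D":
            score += params.delete_extend if prev == "D" else params.delete_open
        else:
            raise ValueError(f"malformed edit operation {op!r}")
        prev = op
    return score


class LabelChangeScorer:
    """Cached label-change scores for one graph's label statistics."""

    def __init__(self, stats: LabelStats, params: ScoringParams, backend: Optional[str] = None):
        self.stats = stats
        self.params = params
        self.backend = backend
        self._cache: dict = {}

    def __call__(self, l1: str, l2: str) -> int:
        key = (l1, l2)
        if key not in self._cache:
            self._cache[key] = label_change_score(
                self.stats, l1, l2, self.params, backend=self.backend
            )
        return self._cache[key]
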