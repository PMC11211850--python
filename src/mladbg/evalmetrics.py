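"""Evaluation: relative scores, greedy reporting, recall, UniFrac profiles.

A reported alignment carries its query interval, score, and per-accession
coverage breakdown (a multi-label alignment distributes its covered query
characters over the labels of its segments).  For a relative-score cut-off
the reported set is the greedy disjoint subset in decreasing relative
score.  Taxonomic profiles weight each accession by its fraction of the
covered query characters; profile error against the ground truth is
classical abundance-weighted UniFrac on the cohort tree (normalized so the
error lies in [0, 1]), and UniFrac accuracy is one minus that error.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.diversity.beta import weighted_unifrac

__all__ = [
    "ReportedAlignment",
    "TaxProfile",
    "SweepResult",
    "select_reported_alignments",
    "coverage",
    "unifrac_accuracy",
    "recall_and_profile_sweep",
    "load_tree",
]

DEFAULT_CUTOFFS = tuple(round(c, 2) for c in np.arange(0.0, 1.0001, 0.02))


@dataclass
class ReportedAlignment:
    """Flat record of one alignment as reported to the user.

    ``intervals`` are the query ranges the alignment actually covers; a
    multi-label alignment with sentinel gaps covers its segments only, so
    other alignments may legitimately be reported inside the gaps.
    """

    query_name: str
    query_length: int
    query_start: int
    query_end: int
    score: int
    label_coverage: dict
    kind: str = "sca"  # "sca" | "mla"
    strand: str = "+"
    intervals: Optional[list] = None

    def __post_init__(self):
        if self.intervals is None:
            self.intervals = [(self.query_start, self.query_end)]

    @property
    def relative_score(self) -> float:
        return self.score / self.query_length

    @property
    def covered(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def overlaps(self, other: "ReportedAlignment") -> bool:
        return any(
            min(e1, e2) - max(s1, s2) > 0
            for s1, e1 in self.intervals
            for s2, e2 in other.intervals
        )

    # -- TSV round trip ------------------------------------------------
    def to_row(self) -> list:
        cov = ",".join(f"{l}:{c}" for l, c in sorted(self.label_coverage.items()))
        ivs = ",".join(f"{s}-{e}" for s, e in self.intervals)
        return [self.query_name, self.query_length, self.strand, self.kind,
                self.query_start, self.query_end, self.score,
                f"{self.relative_score:.4f}", cov, ivs]

    @staticmethod
    def columns() -> list:
        return ["query", "query_length", "strand", "kind", "query_start",
                "query_end", "score", "relative_score", "label_coverage",
                "intervals"]

    @classmethod
    def from_row(cls, row) -> "ReportedAlignment":
        cov = {}
        if row["label_coverage"]:
            for part in str(row["label_coverage"]).split(","):
                label, c = part.rsplit(":", 1)
                cov[label] = int(c)
        ivs = None
        if "intervals" in row and row["intervals"]:
            ivs = [tuple(int(x) for x in part.split("-"))
                   for part in str(row["intervals"]).split(",")]
        return cls(
            query_name=str(row["query"]),
            query_length=int(row["query_length"]),
            query_start=int(row["query_start"]),
            query_end=int(row["query_end"]),
            score=int(row["score"]),
            label_coverage=cov,
            kind=str(row["kind"]),
            strand=str(row["strand"]),
            intervals=ivs,
        )


def select_reported_alignments(alignments: Iterable[ReportedAlignment],
                               cutoff: float) -> list:
    """Greedy disjoint subset with relative score at or above the cut-off.

    Disjointness is judged on covered intervals, so alignments may be
    reported inside another alignment's sentinel gaps.
    """
    ranked = sorted(
        alignments,
        key=lambda a: (-a.relative_score, a.query_start, a.query_end, a.kind),
    )
    kept: list = []
    for a in ranked:
        if a.relative_score < cutoff:
            continue
        if any(a.overlaps(b) for b in kept):
            continue
        kept.append(a)
    return kept


def coverage(selected: list, query_length: int) -> float:
    """Percentage of query characters covered by the (disjoint) selection."""
    if query_length <= 0:
        raise ValueError("query length must be positive")
    return 100.0 * sum(a.covered for a in selected) / query_length


@dataclass
class TaxProfile:
    """Accession -> abundance weight, normalized to sum 1 when non-empty."""

    weights: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("profile weights must be non-negative")
        total = sum(self.weights.values())
        if total > 0:
            self.weights = {l: w / total for l, w in self.weights.items()}

    @classmethod
    def from_alignments(cls, selected: list) -> "TaxProfile":
        acc: dict = {}
        for a in selected:
            for label, chars in a.label_coverage.items():
                acc[label] = acc.get(label, 0) + chars
        return cls(acc)

    @classmethod
    def truth(cls, label: str) -> "TaxProfile":
        return cls({label: 1.0})


def load_tree(newick: str) -> TreeNode:
    tree = TreeNode.read(io.StringIO(newick))
    # weighted UniFrac needs branch lengths everywhere
    for node in tree.traverse():
        if node.length is None:
            node.length = 0.0
    return tree


def unifrac_accuracy(profile: TaxProfile, truth: TaxProfile, tree: TreeNode) -> float:
    """1 - normalized weighted UniFrac between a profile and its truth."""
    leaves = [t.name for t in tree.tips()]
    leafset = set(leaves)
    for label in list(profile.weights) + list(truth.weights):
        if label not in leafset:
            raise KeyError(f"profile leaf {label!r} not in tree")
    scale = 10**6  # integral counts for the distance routine
    u = [int(round(profile.weights.get(l, 0.0) * scale)) for l in leaves]
    v = [int(round(truth.weights.get(l, 0.0) * scale)) for l in leaves]
    err = weighted_unifrac(u, v, taxa=leaves, tree=tree, normalized=True)
    return 1.0 - float(err)


@dataclass
class SweepResult:
    """Recall / accuracy / coverage as functions of the relative-score cut-off."""

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def auarc(self) -> float:
        """Area under the mean accuracy vs recall curve (trapezoidal)."""
        df = self.table.dropna(subset=["mean_unifrac_accuracy"])
        if len(df) < 2:
            return float("nan")
        rec = df["recall"].to_numpy()
        acc = df["mean_unifrac_accuracy"].to_numpy()
        order = np.argsort(rec)
        return float(np.trapezoid(acc[order], rec[order]))


def recall_and_profile_sweep(per_query: list, tree: Optional[TreeNode],
                             cutoffs=DEFAULT_CUTOFFS) -> SweepResult:
    """Sweep the relative-score cut-off over each query's alignment set.

    ``per_query`` holds (query_name, query_length, true_label, alignments)
    tuples.  Recall at a cut-off is the fraction of queries with at least
    one reported alignment; mean UniFrac accuracy averages over mapped
    queries only; mean coverage averages over all queries.
    """
    rows = []
    truths = {}
    for cutoff in cutoffs:
        mapped = 0
        accs = []
        covs = []
        for name, qlen, true_label, alignments in per_query:
            sel = select_reported_alignments(alignments, cutoff)
            covs.append(coverage(sel, qlen))
            if not sel:
                continue
            mapped += 1
            if tree is not None:
                if true_label not in truths:
                    truths[true_label] = TaxProfile.truth(true_label)
                accs.append(
                    unifrac_accuracy(TaxProfile.from_alignments(sel),
                                     truths[true_label], tree)
                )
        rows.append({
            "cutoff": cutoff,
            "recall": mapped / len(per_query) if per_query else 0.0,
            "mean_unifrac_accuracy": float(np.mean(accs)) if accs else np.nan,
            "mean_coverage": float(np.mean(covs)) if covs else 0.0,
        })
    return SweepResult(pd.DataFrame(rows))
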