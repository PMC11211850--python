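"""Annotated De Bruijn graphs with walk covers and suffix queries.

Nodes are k-mers stored as written (non-canonical); edges are implicit
(k-1)-overlaps.  Each node carries a non-empty set of sample labels.  The
graph additionally holds, per label: the node count, a cardinality sketch,
and (built on demand) a walk cover used for constant-time traversal-distance
queries during chaining.  An l-mer suffix index supports seed anchoring and
stands in for the suffix queries of a variable-order DBG.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .hll import make_sketch, sketch_from_dict
from .scoring import LabelStats

logger = logging.getLogger(__name__)

DNA = "ACGT"

__all__ = [
    "AnnotatedDBG",
    "WalkCover",
    "KmerSpectrum",
    "build_annotated_dbg",
    "clean_sample_kmers",
    "build_walk_cover",
    "traversal_distance",
    "suffix_lookup",
    "longest_common_suffix",
    "export_gfa",
    "import_gfa",
    "extract_kmers",
    "node_unitigs",
]


# ---------------------------------------------------------------------------
# k-mer extraction and spectra
# ---------------------------------------------------------------------------

def split_acgt(seq: str):
    """Split a sequence into maximal fragments containing only A/C/G/T."""
    frag = []
    for ch in seq.upper():
        if ch in DNA:
            frag.append(ch)
        elif frag:
            yield "".join(frag)
            frag = []
    if frag:
        yield "".join(frag)


def extract_kmers(sequences, k: int):
    """Yield every k-mer of every ACGT fragment of ``sequences``."""
    for seq in sequences:
        for frag in split_acgt(seq):
            for i in range(len(frag) - k + 1):
                yield frag[i : i + k]


@dataclass
class KmerSpectrum:
    """Multiplicities of the k-mers of one sample's read set."""

    counts: dict

    def __post_init__(self):
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("k-mer multiplicities must be >= 1")

    @classmethod
    def from_reads(cls, reads, k: int) -> "KmerSpectrum":
        counts: dict = {}
        for km in extract_kmers(reads, k):
            counts[km] = counts.get(km, 0) + 1
        return cls(counts)


def noise_threshold(spectrum: KmerSpectrum) -> int:
    """Noise-count threshold: first local minimum of the count histogram.

    A typical spectrum has an error peak at count 1 whose flank falls into
    a valley before the genomic peak; unitigs with median count below the
    valley are treated as noise.  The flank is walked downhill from count 1
    until the histogram rises; if it never rises (monotone histogram, e.g.
    very low depth) there is no separable error peak and the threshold
    falls back to 2.
    """
    if not spectrum.counts:
        raise ValueError("empty spectrum")
    hist: dict = {}
    for c in spectrum.counts.values():
        hist[c] = hist.get(c, 0) + 1
    top = max(hist)
    h = [hist.get(c, 0) for c in range(top + 2)]  # h[c] for c in 0..top+1
    c = 1
    while c < top and h[c + 1] <= h[c]:
        c += 1
    if c == 1 or c == top:  # no declining flank, or it never rises again
        return 2
    return c


# ---------------------------------------------------------------------------
# unitigs
# ---------------------------------------------------------------------------

def _succ(v, nodes):
    tail = v[1:]
    return [tail + c for c in DNA if tail + c in nodes]


def _pred(v, nodes):
    head = v[:-1]
    return [c + head for c in DNA if c + head in nodes]


def node_unitigs(nodes: set) -> list:
    """Decompose a node set into maximal non-branching paths (unitigs).

    Deterministic: unitig starts are visited in lexicographic order, and
    isolated cycles are broken at their lexicographically smallest node.
    """
    starts = []
    for v in nodes:
        preds = _pred(v, nodes)
        if len(preds) != 1 or len(_succ(preds[0], nodes)) != 1:
            starts.append(v)
    unitigs = []
    visited = set()
    for v in sorted(starts):
        path = [v]
        visited.add(v)
        cur = v
        while True:
            nxt = _succ(cur, nodes)
            if len(nxt) != 1:
                break
            nxt = nxt[0]
            if nxt in visited or len(_pred(nxt, nodes)) != 1:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        unitigs.append(path)
    # isolated cycles: every node has in/out degree exactly 1
    for v in sorted(nodes - visited):
        if v in visited:
            continue
        path = [v]
        visited.add(v)
        cur = v
        while True:
            nxt = _succ(cur, nodes)[0]
            if nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        unitigs.append(path)
    return unitigs


def spelled_length(unitig: list, k: int) -> int:
    return k + len(unitig) - 1


def clean_sample_kmers(spectrum: KmerSpectrum, k: int,
                       threshold: int | None = None) -> set:
    """Assembly-style cleaning of one sample's k-mer set.

    1. pick a noise-count threshold from the count histogram (or take the
       explicit ``threshold`` override);
    2. drop unitigs whose median k-mer multiplicity is below the threshold;
    3. clip tips: dead-end unitigs spelling fewer than 2k characters that
       hang off a remaining junction (isolated fragments are kept -- at low
       depth they are the signal, not noise).
    """
    thr = noise_threshold(spectrum) if threshold is None else threshold
    nodes = set(spectrum.counts)
    survivors = set()
    for unitig in node_unitigs(nodes):
        counts = sorted(spectrum.counts[v] for v in unitig)
        median = counts[len(counts) // 2] if len(counts) % 2 else (
            (counts[len(counts) // 2 - 1] + counts[len(counts) // 2]) / 2
        )
        if median >= thr:
            survivors.update(unitig)
    # tip clipping on the surviving graph
    kept = set(survivors)
    for unitig in node_unitigs(survivors):
        if spelled_length(unitig, k) >= 2 * k:
            continue
        first, last = unitig[0], unitig[-1]
        outside = set(survivors) - set(unitig)
        dead_start = not any(u in outside for u in _pred(first, survivors))
        dead_end = not any(u in outside for u in _succ(last, survivors))
        if dead_start != dead_end:  # dead at exactly one end: a true tip
            kept.difference_update(unitig)
    return kept


# ---------------------------------------------------------------------------
# walk covers
# ---------------------------------------------------------------------------

UNKNOWN = None  # traversal distance sentinel


@dataclass
class WalkCover:
    """A set of walks jointly visiting every node of one label's subgraph.

    ``node_index`` maps each node to its (walk id, offset) memberships,
    giving constant-time traversal-distance queries during chaining.
    """

    label: str
    walks: list
    node_index: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.node_index:
            for wid, walk in enumerate(self.walks):
                for off, v in enumerate(walk):
                    self.node_index.setdefault(v, []).append((wid, off))

    def traversal_distance(self, v1: str, v2: str):
        """Min offset difference along a shared walk, or UNKNOWN (None)."""
        m1 = self.node_index.get(v1)
        m2 = self.node_index.get(v2)
        if m1 is None or m2 is None:
            raise KeyError("node absent from walk cover")
        best = None
        offs2: dict = {}
        for wid, off in m2:
            lst = offs2.setdefault(wid, [])
            lst.append(off)
        for wid, o1 in m1:
            for o2 in offs2.get(wid, ()):
                if o2 >= o1 and (best is None or o2 - o1 < best):
                    best = o2 - o1
        return best

    def walk_slice(self, v1: str, v2: str):
        """Node path realising the minimal traversal distance, or None."""
        best = None
        offs2: dict = {}
        for wid, off in self.node_index.get(v2, ()):
            offs2.setdefault(wid, []).append(off)
        for wid, o1 in self.node_index.get(v1, ()):
            for o2 in offs2.get(wid, ()):
                if o2 >= o1 and (best is None or o2 - o1 < best[2] - best[1]):
                    best = (wid, o1, o2)
        if best is None:
            return None
        wid, o1, o2 = best
        return self.walks[wid][o1 : o2 + 1]

    @property
    def width(self) -> int:
        return len(self.walks)


def build_walk_cover(graph: "AnnotatedDBG", label: str) -> WalkCover:
    """Greedy unitig-joining walk cover of one label's subgraph.

    Maximal unitigs are joined across branch nodes (lexicographically
    smallest eligible successor first, deterministic), then one extra
    two-node walk is added per edge not realised by any stored walk so that
    branch edges remain traversable.
    """
    if label not in graph.label_nodes:
        raise KeyError(f"unknown label {label!r}")
    nodes = graph.label_nodes[label]
    unitigs = node_unitigs(nodes)
    start_of = {u[0]: i for i, u in enumerate(unitigs)}
    used = [False] * len(unitigs)
    walks = []
    for i, unitig in enumerate(unitigs):
        if used[i]:
            continue
        used[i] = True
        walk = list(unitig)
        while True:
            candidates = [
                w for w in _succ(walk[-1], nodes)
                if w in start_of and not used[start_of[w]]
            ]
            if not candidates:
                break
            j = start_of[min(candidates)]
            used[j] = True
            walk.extend(unitigs[j])
        walks.append(walk)
    covered_edges = set()
    for walk in walks:
        for a, b in zip(walk, walk[1:]):
            covered_edges.add((a, b))
    for v in sorted(nodes):
        for w in _succ(v, nodes):
            if (v, w) not in covered_edges:
                walks.append([v, w])
                covered_edges.add((v, w))
    return WalkCover(label, walks)


def traversal_distance(cover: WalkCover, v1: str, v2: str):
    return cover.traversal_distance(v1, v2)


# ---------------------------------------------------------------------------
# the annotated graph
# ---------------------------------------------------------------------------

class AnnotatedDBG:
    """Node-centric order-k DBG with per-node label sets.

    Edges are implicit: (v1, v2) is an edge iff v1[1:] == v2[:-1].  The
    suffix index is built for one configured seed length l and maps each
    l-mer to the nodes whose length-l suffix equals it.
    """

    def __init__(self, k: int, seed_length: int, sketch_backend: str = "hll",
                 sketch_error: float = 0.05):
        if not 1 <= seed_length <= k:
            raise ValueError("seed length must satisfy 1 <= l <= k")
        self.k = k
        self.seed_length = seed_length
        self.sketch_backend = sketch_backend
        self.sketch_error = sketch_error
        self.annotation: dict = {}      # node -> set of labels
        self.label_nodes: dict = {}     # label -> set of nodes
        self.label_sizes: dict = {}
        self.label_sketches: dict = {}
        self.suffix_index: dict = {}    # l-mer -> list of nodes
        self.covers: dict = {}          # label -> WalkCover (lazy)

    # -- construction --------------------------------------------------
    @classmethod
    def from_label_kmer_sets(cls, label_sets: dict, k: int, seed_length: int,
                             sketch_backend: str = "hll",
                             sketch_error: float = 0.05) -> "AnnotatedDBG":
        g = cls(k, seed_length, sketch_backend, sketch_error)
        for label, kmers in label_sets.items():
            if not kmers:
                raise ValueError(f"label {label!r} has zero nodes")
            g.label_nodes[label] = set(kmers)
            for km in kmers:
                if len(km) != k:
                    raise ValueError(f"node {km!r} does not have length k={k}")
                g.annotation.setdefault(km, set()).add(label)
        for node in g.annotation:
            g.suffix_index.setdefault(node[k - seed_length:], []).append(node)
        for lmer in g.suffix_index:
            g.suffix_index[lmer].sort()
        for label, kmers in g.label_nodes.items():
            g.label_sizes[label] = len(kmers)
            sk = make_sketch(sketch_backend, sketch_error)
            sk.update(kmers)
            g.label_sketches[label] = sk
        return g

    # -- basic queries -------------------------------------------------
    @property
    def nodes(self):
        return self.annotation.keys()

    @property
    def labels(self):
        return sorted(self.label_nodes)

    def __contains__(self, node: str) -> bool:
        return node in self.annotation

    def has_edge(self, v1: str, v2: str) -> bool:
        return v1 in self.annotation and v2 in self.annotation and v1[1:] == v2[:-1]

    def out_neighbors(self, v: str, label: str | None = None):
        pool = self.annotation if label is None else self.label_nodes[label]
        return _succ(v, pool)

    def in_neighbors(self, v: str, label: str | None = None):
        pool = self.annotation if label is None else self.label_nodes[label]
        return _pred(v, pool)

    def suffix_lookup(self, lmer: str):
        """All (node, label) pairs whose node has l-suffix ``lmer``."""
        if len(lmer) != self.seed_length:
            raise ValueError(
                f"seed length mismatch: got {len(lmer)}, index built for {self.seed_length}"
            )
        out = set()
        for node in self.suffix_index.get(lmer, ()):
            for label in self.annotation[node]:
                out.add((node, label))
        return out

    def get_cover(self, label: str) -> WalkCover:
        if label not in self.covers:
            self.covers[label] = build_walk_cover(self, label)
        return self.covers[label]

    def build_all_covers(self) -> None:
        for label in self.labels:
            self.get_cover(label)

    def label_stats(self, with_exact: bool = True) -> LabelStats:
        return LabelStats(
            sizes=dict(self.label_sizes),
            sketches=dict(self.label_sketches),
            total=len(self.annotation),
            exact_sets=dict(self.label_nodes) if with_exact else None,
        )

    # -- serialisation -------------------------------------------------
    def to_json(self, path) -> None:
        data = {
            "k": self.k,
            "seed_length": self.seed_length,
            "sketch_backend": self.sketch_backend,
            "sketch_error": self.sketch_error,
            "labels": {
                label: sorted(nodes) for label, nodes in self.label_nodes.items()
            },
            "sketches": {l: sk.to_dict() for l, sk in self.label_sketches.items()},
            "covers": {l: c.walks for l, c in self.covers.items()},
        }
        with open(path, "w") as fh:
            json.dump(data, fh)

    @classmethod
    def from_json(cls, path) -> "AnnotatedDBG":
        with open(path) as fh:
            data = json.load(fh)
        g = cls.from_label_kmer_sets(
            data["labels"], data["k"], data["seed_length"],
            data["sketch_backend"], data["sketch_error"],
        )
        g.label_sketches = {l: sketch_from_dict(d) for l, d in data["sketches"].items()}
        g.covers = {l: WalkCover(l, walks) for l, walks in data["covers"].items()}
        return g


def build_annotated_dbg(sample_sequences: dict, k: int, seed_length: int,
                        sketch_backend: str = "hll",
                        sketch_error: float = 0.05) -> AnnotatedDBG:
    """Build an annotated DBG from per-sample sequence lists.

    Non-ACGT characters split sequences into clean fragments before k-mer
    extraction.  A label whose sequences yield no k-mer raises.
    """
    label_sets = {}
    for label, seqs in sample_sequences.items():
        if not seqs:
            raise ValueError(f"label {label!r} has no sequences")
        kmers = set(extract_kmers(seqs, k))
        if not kmers:
            raise ValueError(
                f"label {label!r}: every sequence is shorter than k={k}"
            )
        label_sets[label] = kmers
    return AnnotatedDBG.from_label_kmer_sets(
        label_sets, k, seed_length, sketch_backend, sketch_error
    )


def suffix_lookup(graph: AnnotatedDBG, lmer: str):
    return graph.suffix_lookup(lmer)


def longest_common_suffix(v1: str, v2: str) -> int:
    """Length of the longest shared suffix of two equal-length nodes."""
    if len(v1) != len(v2):
        raise ValueError("nodes must have equal length")
    n = 0
    for a, b in zip(reversed(v1), reversed(v2)):
        if a != b:
            break
        n += 1
    return n


# ---------------------------------------------------------------------------
# GFA 1.0 export / import
# ---------------------------------------------------------------------------

def _label_uniform_unitigs(graph: AnnotatedDBG):
    """Whole-graph unitigs split wherever the node label set changes."""
    for unitig in node_unitigs(set(graph.annotation)):
        run = [unitig[0]]
        for v in unitig[1:]:
            if graph.annotation[v] == graph.annotation[run[-1]]:
                run.append(v)
            else:
                yield run
                run = [v]
        yield run


def export_gfa(graph: AnnotatedDBG, path) -> None:
    """Write GFA 1.0: label-uniform unitigs as segments, (k-1)M links.

    Label sets travel in a ``LB:Z:`` tag; re-import reproduces the node and
    label sets exactly.
    """
    k = graph.k
    segments = list(_label_uniform_unitigs(graph))
    seg_of_first = {}
    seg_of_last = {}
    with open(path, "w") as fh:
        fh.write(f"H\tVN:Z:1.0\tKL:i:{k}\n")
        for idx, seg in enumerate(segments):
            name = f"s{idx + 1}"
            spelling = seg[0] + "".join(v[-1] for v in seg[1:])
            labels = ",".join(sorted(graph.annotation[seg[0]]))
            fh.write(f"S\t{name}\t{spelling}\tLB:Z:{labels}\n")
            seg_of_first[seg[0]] = name
            seg_of_last[name] = seg[-1]
        for name, last in seg_of_last.items():
            for nxt in _succ(last, graph.annotation):
                if nxt in seg_of_first:
                    fh.write(f"L\t{name}\t+\t{seg_of_first[nxt]}\t+\t{k - 1}M\n")


def import_gfa(path, seed_length: int, sketch_backend: str = "hll",
               sketch_error: float = 0.05) -> AnnotatedDBG:
    k = None
    label_sets: dict = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "H":
                for tag in parts[1:]:
                    if tag.startswith("KL:i:"):
                        k = int(tag[5:])
            elif parts[0] == "S":
                spelling = parts[2]
                labels = []
                for tag in parts[3:]:
                    if tag.startswith("LB:Z:"):
                        labels = tag[5:].split(",")
                if k is None:
                    raise ValueError("GFA header lacks the KL:i graph-order tag")
                for label in labels:
                    label_sets.setdefault(label, set()).update(
                        extract_kmers([spelling], k)
                    )
    if k is None:
        raise ValueError("not a graph archive produced by export_gfa")
    return AnnotatedDBG.from_label_kmer_sets(
        label_sets, k, seed_length, sketch_backend, sketch_error
    )
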