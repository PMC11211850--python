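"""End-to-end alignment of reads against an annotated graph.

Ties the stages together: both query orientations are aligned
independently and all resulting records are reported (k-mers are stored as
written, so the reverse complement is a separate query).  Three modes
mirror the method ladder: ``sca`` reports the single-label pool only;
``sca+lc`` adds multi-label chaining with label changes but no node-length
changes; ``sca+lc+nc`` is the full multi-label model.  Multi-label modes
report the pool alignments alongside the stitched multi-label alignments
-- a single-label alignment is a degenerate multi-label one, so the
multi-label reportable set subsumes the single-label one.
"""

from __future__ import annotations

from typing import Optional

from .evalmetrics import ReportedAlignment
from .graph import AnnotatedDBG
from .mlc import align_multi_label
from .sca import align_single_label
from .scoring import LabelStats, ScoringParams
from .simdata import revcomp

MODES = ("sca", "sca+lc", "sca+lc+nc")

__all__ = ["MODES", "align_query", "evaluate_queries"]


def _flip(start: int, end: int, qlen: int):
    return qlen - end, qlen - start


def align_query(graph: AnnotatedDBG, query: str, params: ScoringParams,
                mode: str = "sca+lc+nc", stats: Optional[LabelStats] = None,
                name: str = "query") -> list:
    """Align one read (both orientations) and return reported records."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if stats is None and mode != "sca":
        stats = graph.label_stats()
    qlen = len(query)
    records = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        pool = align_single_label(q, graph, params)
        for aln in pool:
            qs, qe = aln.query_start, aln.query_end
            if strand == "-":
                qs, qe = _flip(qs, qe, qlen)
            records.append(ReportedAlignment(
                name, qlen, qs, qe, aln.score,
                {aln.label: aln.length}, kind="sca", strand=strand,
            ))
        if mode == "sca" or not pool:
            continue
        mparams = params.with_(
            allow_node_length_change=(mode == "sca+lc+nc")
        )
        for mla in align_multi_label(q, graph, mparams, pool=pool, stats=stats):
            qs, qe = mla.query_start, mla.query_end
            ivs = [(s.query_start, s.query_end) for s in mla.segments]
            if strand == "-":
                qs, qe = _flip(qs, qe, qlen)
                ivs = sorted(_flip(s, e, qlen) for s, e in ivs)
            records.append(ReportedAlignment(
                name, qlen, qs, qe, mla.score,
                mla.label_coverage(), kind="mla", strand=strand,
                intervals=ivs,
            ))
    records.sort(key=lambda r: (-r.score, r.query_start, r.kind, r.strand))
    return records


def evaluate_queries(graph: AnnotatedDBG, queries: list, params: ScoringParams,
                     mode: str) -> list:
    """Per-query alignment records for a sweep: (name, len, truth, records)."""
    stats = graph.label_stats() if mode != "sca" else None
    out = []
    for read in queries:
        records = align_query(graph, read.seq, params, mode=mode, stats=stats,
                              name=read.name)
        out.append((read.name, len(read.seq), read.label, records))
    return out
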