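"""Synthetic cohorts: related genomes, low-depth reads, fragmented graphs.

The generator emulates the setting the aligner targets: a clade of related
genomes evolved down a random binary tree, per-sample read sets at low
sequencing depth with platform-like error profiles, per-sample k-mer
cleaning, and a merged annotated graph whose per-label subgraphs are
fragmented.  The simulation tree doubles as the taxonomy used for
evaluation, with one leaf per sample accession.

Everything is deterministic under the supplied seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .graph import AnnotatedDBG, KmerSpectrum, clean_sample_kmers

logger = logging.getLogger(__name__)

DNA = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

__all__ = [
    "ReadProfile",
    "PROFILES",
    "SimRead",
    "SimulatedCohort",
    "simulate_related_genomes",
    "simulate_reads",
    "simulate_queries",
    "build_cohort_graph",
    "simulate_cohort",
    "write_cohort",
]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ReadProfile:
    """Parametric read simulator settings (length range and error rates)."""

    name: str
    min_length: int
    max_length: int
    sub_rate: float
    ins_rate: float
    del_rate: float

    @property
    def error_rate(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate


#: Named profiles standing in for common platforms: short accurate reads,
#: error-prone long reads, and accurate long reads.
PROFILES = {
    "short-accurate": ReadProfile("short-accurate", 150, 150, 1e-3, 1e-4, 1e-4),
    "long-noisy": ReadProfile("long-noisy", 5000, 20000, 0.06, 0.02, 0.02),
    "long-accurate": ReadProfile("long-accurate", 5000, 20000, 4e-3, 5e-4, 5e-4),
}


@dataclass
class SimRead:
    name: str
    seq: str
    label: str
    origin_start: int
    origin_end: int
    strand: str = "+"


@dataclass
class SimulatedCohort:
    genomes: dict
    tree_newick: str
    read_sets: dict = field(default_factory=dict)
    depths: dict = field(default_factory=dict)
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# genome evolution
# ---------------------------------------------------------------------------

def _random_genome(length: int, rng) -> str:
    return "".join(np.array(list(DNA))[rng.integers(0, 4, size=length)])

def mutate(seq: str, sub_rate: float, ins_rate: float, del_rate: float, rng) -> str:
    """Apply iid substitutions and short (1-3 bp) indels to a sequence."""
    out = []
    u = rng.random(len(seq))
    v = rng.random(len(seq))
    for i, ch in enumerate(seq):
        r = u[i]
        if r < del_rate:
            continue
        r -= del_rate
        if r < sub_rate:
            out.append(DNA[(DNA.index(ch) + 1 + int(rng.integers(0, 3))) % 4])
        else:
            out.append(ch)
        if v[i] < ins_rate:
            out.append("".join(DNA[rng.integers(0, 4)]
                               for _ in range(1 + int(rng.integers(0, 3)))))
    return "".join(out)


def _random_topology(labels: list, rng):
    """Random recursive bifurcation; returns a nested-tuple tree."""
    if len(labels) == 1:
        return labels[0]
    cut = 1 + int(rng.integers(0, len(labels) - 1))
    idx = list(rng.permutation(len(labels)))
    left = [labels[i] for i in sorted(idx[:cut])]
    right = [labels[i] for i in sorted(idx[cut:])]
    return (_random_topology(left, rng), _random_topology(right, rng))


def _to_newick(node, branch: float) -> str:
    if isinstance(node, str):
        return f"{node}:{branch:g}"
    left, right = node
    return f"({_to_newick(left, branch)},{_to_newick(right, branch)}):{branch:g}"


def simulate_related_genomes(n: int, length: int, divergence_per_branch: float,
                             seed: int, indel_fraction: float = 0.1) -> SimulatedCohort:
    """Evolve ``n`` genomes from a random root down a random binary tree.

    Each branch applies substitutions at ``divergence_per_branch`` per site
    plus short indels at a tenth of that rate, so pairwise identity decays
    with tree distance.
    """
    if n < 2:
        raise ValueError("need at least two genomes")
    if not 0 <= divergence_per_branch <= 0.5:
        raise ValueError("divergence per branch must be in [0, 0.5]")
    if length < 300:
        raise ValueError("genome length too short to be meaningful")
    rng = np.random.default_rng(seed)
    labels = [f"s{i + 1:02d}" for i in range(n)]
    topo = _random_topology(labels, rng)
    root = _random_genome(length, rng)
    genomes: dict = {}

    indel = divergence_per_branch * indel_fraction

    def descend(node, seq):
        if isinstance(node, str):
            genomes[node] = seq
            return
        for child in node:
            descend(child, mutate(seq, divergence_per_branch, indel, indel, rng))

    descend(topo, root)
    newick = (
        f"({_to_newick(topo[0], divergence_per_branch)},"
        f"{_to_newick(topo[1], divergence_per_branch)});"
    )
    return SimulatedCohort(genomes=genomes, tree_newick=newick, seed=seed)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(genome: str, depth: float, profile: ReadProfile, seed,
                   label: str = "sample", name_prefix: str = "r") -> list:
    """Sample reads until total bases reach ``depth * |genome|`` (+-1 read)."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if profile.min_length > len(genome):
        raise ValueError("read length exceeds genome length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target = depth * len(genome)
    total = 0
    reads = []
    while total < target:
        if profile.min_length == profile.max_length:
            L = profile.min_length
        else:
            # log-uniform length within the profile's range
            L = int(np.exp(rng.uniform(np.log(profile.min_length),
                                       np.log(profile.max_length))))
        L = min(L, len(genome))
        start = int(rng.integers(0, len(genome) - L + 1))
        frag = genome[start : start + L]
        strand = "+" if rng.random() < 0.5 else "-"
        seq = mutate(frag, profile.sub_rate, profile.ins_rate, profile.del_rate, rng)
        if strand == "-":
            seq = revcomp(seq)
        reads.append(SimRead(f"{name_prefix}{len(reads)}", seq, label,
                             start, start + L, strand))
        total += L
    return reads


def simulate_queries(cohort: SimulatedCohort, n_queries: int, profile: ReadProfile,
                     seed: int) -> list:
    """Draw query reads uniformly from the cohort's genomes."""
    rng = np.random.default_rng(seed)
    labels = sorted(cohort.genomes)
    queries = []
    for qi in range(n_queries):
        label = labels[int(rng.integers(0, len(labels)))]
        reads = simulate_reads(cohort.genomes[label], 1e-9, profile, rng,
                               label=label, name_prefix=f"q{qi}_")
        # depth ~ 0 yields exactly one read
        r = reads[0]
        queries.append(SimRead(f"q{qi}", r.seq, label, r.origin_start,
                               r.origin_end, r.strand))
    return queries


def simulate_cohort(n: int = 6, length: int = 50_000,
                    divergence_per_branch: float = 0.02,
                    depth_range=(1.0, 2.0),
                    profile: str | ReadProfile = "short-accurate",
                    seed: int = 0) -> SimulatedCohort:
    """Full cohort: genomes, tree, and per-sample read sets at low depth."""
    cohort = simulate_related_genomes(n, length, divergence_per_branch, seed)
    prof = PROFILES[profile] if isinstance(profile, str) else profile
    rng = np.random.default_rng([seed, 1])
    for label in sorted(cohort.genomes):
        depth = float(rng.uniform(*depth_range))
        cohort.depths[label] = depth
        cohort.read_sets[label] = simulate_reads(
            cohort.genomes[label], depth, prof, rng, label=label,
            name_prefix=f"{label}_r",
        )
    return cohort


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def build_cohort_graph(cohort: SimulatedCohort, k: int, seed_length: int,
                       sketch_backend: str = "hll", sketch_error: float = 0.05,
                       clean: bool = True) -> AnnotatedDBG:
    """Per-sample spectrum -> cleaning -> merged annotated graph with covers.

    Spectra are strand-symmetric (each read is counted together with its
    reverse complement), matching how canonical-k-mer graph builders treat
    double-stranded read sets; without this, reads split over the two
    strands would halve the effective per-orientation depth.
    """
    label_sets = {}
    for label, reads in sorted(cohort.read_sets.items()):
        seqs = [r.seq for r in reads]
        spectrum = KmerSpectrum.from_reads(seqs + [revcomp(s) for s in seqs], k)
        if not spectrum.counts:
            logger.warning("sample %s yields no k-mers; label dropped", label)
            continue
        kmers = clean_sample_kmers(spectrum, k) if clean else set(spectrum.counts)
        if not kmers:
            logger.warning("sample %s cleaned to emptiness; label dropped", label)
            continue
        label_sets[label] = kmers
    if not label_sets:
        raise ValueError("every sample cleaned to emptiness")
    graph = AnnotatedDBG.from_label_kmer_sets(
        label_sets, k, seed_length, sketch_backend, sketch_error
    )
    graph.build_all_covers()
    return graph


# ---------------------------------------------------------------------------
# on-disk artefacts
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, outdir) -> None:
    """Write genomes (FASTA), reads (FASTQ), tree (Newick), and a manifest."""
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "genomes.fasta"), "w") as fh:
        for label in sorted(cohort.genomes):
            fh.write(f">{label}\n{cohort.genomes[label]}\n")
    for label, reads in sorted(cohort.read_sets.items()):
        with open(os.path.join(outdir, f"{label}.fastq"), "w") as fh:
            for r in reads:
                fh.write(f"@{r.name} origin={r.origin_start}-{r.origin_end}"
                         f" strand={r.strand}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")
    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(cohort.tree_newick + "\n")
    manifest = {
        "seed": cohort.seed,
        "samples": {
            label: {
                "depth": cohort.depths.get(label),
                "reads": len(cohort.read_sets.get(label, [])),
                "genome_length": len(cohort.genomes[label]),
            }
            for label in sorted(cohort.genomes)
        },
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
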