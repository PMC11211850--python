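import random

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mladbg.graph import build_annotated_dbg
from mladbg.scoring import ScoringParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DNA = "ACGT"


def random_seq(rng, n: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, n))


def mutate_seq(seq: str, rate: float, rng: random.Random,
               sub_frac: float = 0.6, del_frac: float = 0.2) -> str:
    """Point mutations: substitutions, deletions, and 1-2 bp insertions."""
    out = []
    for ch in seq:
        r = rng.random()
        if r < rate * sub_frac:
            out.append(DNA[(DNA.index(ch) + rng.randint(1, 3)) % 4])
        elif r < rate * (sub_frac + del_frac):
            continue
        elif r < rate:
            out.append(ch + rng.choice(DNA) * rng.randint(1, 2))
        else:
            out.append(ch)
    return "".join(out)


@pytest.fixture
def toy_params():
    return ScoringParams(k=21, seed_length=11)


@pytest.fixture
def linear_graph(toy_params):
    """Single-label graph over one 1.2 kb random genome (one walk)."""
    rng = np.random.default_rng(42)
    genome = random_seq(rng, 1200)
    g = build_annotated_dbg({"s1": [genome]}, toy_params.k, toy_params.seed_length)
    g.build_all_covers()
    return g, genome


@pytest.fixture
def fragmented_pair_graph(toy_params):
    """Two related samples whose fragments jointly tile a root genome.

    Sample A keeps the flanks of its mutated copy, sample B the middle, so
    a query spanning A's hole needs a label change to stay covered.
    """
    rng = np.random.default_rng(7)
    pyrng = random.Random(7)
    root = random_seq(rng, 3000)
    gA = mutate_seq(root, 0.02, pyrng)
    gB = mutate_seq(root, 0.02, pyrng)
    samples = {"A": [gA[:1200], gA[1800:]], "B": [gB[800:2200]]}
    g = build_annotated_dbg(samples, toy_params.k, toy_params.seed_length)
    g.build_all_covers()
    return g, root
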