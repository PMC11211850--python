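import numpy as np
import pytest
from hypothesis import given, strategies as st

from mladbg.graph import (
    AnnotatedDBG,
    KmerSpectrum,
    build_annotated_dbg,
    build_walk_cover,
    clean_sample_kmers,
    export_gfa,
    import_gfa,
    longest_common_suffix,
    node_unitigs,
    noise_threshold,
    suffix_lookup,
    traversal_distance,
)

from conftest import random_seq


class TestBuild:
    def test_kmer_extraction(self):
        g = build_annotated_dbg({"l1": ["ACGTA"]}, 4, 3)
        assert set(g.nodes) == {"ACGT", "CGTA"}
        assert g.annotation["ACGT"] == {"l1"} and g.annotation["CGTA"] == {"l1"}

    def test_shared_node_unions_labels(self):
        g = build_annotated_dbg({"l1": ["ACGT"], "l2": ["ACGT"]}, 4, 3)
        assert set(g.nodes) == {"ACGT"}
        assert g.annotation["ACGT"] == {"l1", "l2"}
        assert g.label_sizes == {"l1": 1, "l2": 1}

    def test_implicit_edge_requires_k_minus_1_overlap(self):
        # the toy graph: GGCA and CACC do not overlap by k-1, so no edge
        g = build_annotated_dbg({"y": ["TGGCA"], "b": ["CACCG"]}, 4, 3)
        assert not g.has_edge("GGCA", "CACC")
        assert g.has_edge("TGGC", "GGCA")

    def test_too_short_label_errors(self):
        with pytest.raises(ValueError, match="shorter than k"):
            build_annotated_dbg({"l1": ["ACG"]}, 4, 3)

    def test_non_acgt_splits_fragments(self):
        g = build_annotated_dbg({"l1": ["ACGTNNACGTT"]}, 4, 3)
        # N breaks the sequence; no k-mer spans it
        assert set(g.nodes) == {"ACGT", "CGTT"}

    def test_empty_label_errors(self):
        with pytest.raises(ValueError):
            build_annotated_dbg({"l1": []}, 4, 3)


class TestSuffixIndex:
    def test_lookup_expands_labels(self):
        g = build_annotated_dbg({"l1": ["ACGT"], "l2": ["TCGT"]}, 4, 3)
        assert suffix_lookup(g, "CGT") == {("ACGT", "l1"), ("TCGT", "l2")}
        assert suffix_lookup(g, "AAA") == set()

    def test_wrong_seed_length_errors(self):
        g = build_annotated_dbg({"l1": ["ACGT"]}, 4, 3)
        with pytest.raises(ValueError, match="seed length"):
            suffix_lookup(g, "ACGT")

    def test_full_length_suffix_is_the_node(self):
        g = build_annotated_dbg({"l1": ["ACGT"], "l2": ["ACGT"]}, 4, 4)
        assert suffix_lookup(g, "ACGT") == {("ACGT", "l1"), ("ACGT", "l2")}

    @given(st.integers(0, 2**32 - 1))
    def test_completeness_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = build_annotated_dbg(
            {"a": [random_seq(rng, 60)], "b": [random_seq(rng, 60)]}, 8, 5
        )
        for node, labels in g.annotation.items():
            hits = g.suffix_lookup(node[-5:])
            for label in labels:
                assert (node, label) in hits


class TestLongestCommonSuffix:
    @pytest.mark.parametrize(
        "v1,v2,want",
        [("TCTG", "AATG", 2), ("ACGT", "ACGT", 4), ("AAAA", "CCCC", 0)],
    )
    def test_examples(self, v1, v2, want):
        assert longest_common_suffix(v1, v2) == want

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            longest_common_suffix("ACG", "ACGT")


class TestCleaning:
    def test_uniform_counts_all_retained(self):
        rng = np.random.default_rng(0)
        genome = random_seq(rng, 40)  # >= 3k for k=5
        spec = KmerSpectrum({genome[i : i + 5]: 10 for i in range(36)})
        assert clean_sample_kmers(spec, 5) == set(spec.counts)

    def test_short_tip_pruned_backbone_kept(self):
        rng = np.random.default_rng(1)
        k = 7
        while True:  # a backbone without repeated (k-1)-mers: one clean unitig
            backbone = random_seq(rng, 120)
            kmers = [backbone[i : i + k - 1] for i in range(len(backbone) - k + 2)]
            if len(set(kmers)) == len(kmers):
                break
        # branch shares one k-mer with the backbone then diverges; its
        # spelled length stays below 2k
        branch = backbone[40:47] + "ACAC"
        counts = {}
        for seq in (backbone, branch):
            for i in range(len(seq) - k + 1):
                counts[seq[i : i + k]] = counts.get(seq[i : i + k], 0) + 10
        spec = KmerSpectrum(counts)
        kept = clean_sample_kmers(spec, k)
        backbone_kmers = {backbone[i : i + k] for i in range(len(backbone) - k + 1)}
        branch_only = set(counts) - backbone_kmers
        assert branch_only and not (kept & branch_only)
        assert backbone_kmers <= kept

    def test_low_median_unitig_discarded(self):
        # histogram with a valley at 2: 3 k-mers at count 1, 2 at count 2,
        # many at count 3 -> threshold 2; the count-1 unitig dies
        rng = np.random.default_rng(2)
        k = 5
        weak = random_seq(rng, 7)  # 3 k-mers
        strong = random_seq(rng, 20)  # 16 k-mers
        counts = {weak[i : i + k]: 1 for i in range(3)}
        skmers = [strong[i : i + k] for i in range(16) if strong[i : i + k] not in counts]
        for i, km in enumerate(skmers):
            counts[km] = 2 if i < 2 else 3
        spec = KmerSpectrum(counts)
        assert noise_threshold(spec) == 2
        kept = clean_sample_kmers(spec, k)
        assert not (kept & {weak[i : i + k] for i in range(3)})

    def test_monotone_histogram_falls_back_to_2(self):
        spec = KmerSpectrum({"AAAAA": 1, "AAAAT": 1, "CCCCC": 2})
        assert noise_threshold(spec) == 2

    def test_threshold_monotonicity(self):
        # disjoint linear fragments (no junctions, so no tip interactions):
        # raising the noise threshold can only shrink the survivor set
        rng = np.random.default_rng(3)
        k = 8
        while True:  # one backbone with unique (k-1)-mers, sliced into pieces
            base = random_seq(rng, 620)
            sub = [base[i : i + k - 1] for i in range(len(base) - k + 2)]
            if len(set(sub)) == len(sub):
                break
        counts = {}
        for fi in range(12):
            frag = base[fi * 50 : fi * 50 + 40]
            c = int(rng.integers(1, 6))
            for i in range(len(frag) - k + 1):
                counts[frag[i : i + k]] = c
        spec = KmerSpectrum(counts)
        prev = None
        for thr in (1, 2, 3, 4, 5):
            kept = clean_sample_kmers(spec, k, threshold=thr)
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestWalkCover:
    def test_linear_subgraph_single_walk(self):
        rng = np.random.default_rng(4)
        genome = random_seq(rng, 50)
        g = build_annotated_dbg({"a": [genome]}, 6, 4)
        cover = build_walk_cover(g, "a")
        assert cover.width == 1
        assert set(cover.walks[0]) == g.label_nodes["a"]

    def test_disconnected_unitigs_two_walks(self):
        g = build_annotated_dbg({"a": ["ACGTACG", "TTGCATT"]}, 6, 4)
        cover = build_walk_cover(g, "a")
        assert cover.width >= 2
        covered = set().union(*(set(w) for w in cover.walks))
        assert covered == g.label_nodes["a"]

    def test_unknown_label_errors(self, linear_graph):
        g, _ = linear_graph
        with pytest.raises(KeyError):
            build_walk_cover(g, "nope")

    @pytest.mark.parametrize("seed", range(5))
    def test_cover_soundness_random(self, seed):
        rng = np.random.default_rng(seed)
        seqs = [random_seq(rng, int(rng.integers(20, 80))) for _ in range(3)]
        g = build_annotated_dbg({"a": seqs}, 8, 5)
        cover = build_walk_cover(g, "a")
        # every node covered, walks edge-consistent, index agrees
        covered = set()
        for wid, walk in enumerate(cover.walks):
            for off, (u) in enumerate(walk):
                covered.add(u)
                assert (wid, off) in cover.node_index[u]
            for u, v in zip(walk, walk[1:]):
                assert u[1:] == v[:-1]
        assert covered == g.label_nodes["a"]

    def test_traversal_distances(self):
        rng = np.random.default_rng(6)
        genome = random_seq(rng, 60)
        g = build_annotated_dbg({"a": [genome, "TTTTTTTTTT"]}, 6, 4)
        cover = build_walk_cover(g, "a")
        walk = cover.walks[0]
        assert traversal_distance(cover, walk[0], walk[0]) == 0
        assert traversal_distance(cover, walk[0], walk[1]) == 1
        assert traversal_distance(cover, walk[3], walk[1]) is None  # wrong order
        # nodes on different walks are unreachable through the cover
        assert traversal_distance(cover, walk[0], "TTTTTT") is None
        with pytest.raises(KeyError):
            traversal_distance(cover, "ACACAC", walk[0])


class TestGfa:
    def test_two_node_linear_graph(self, tmp_path):
        g = build_annotated_dbg({"a": ["ACGTA"]}, 4, 3)
        path = tmp_path / "g.gfa"
        export_gfa(g, path)
        lines = path.read_text().splitlines()
        assert sum(1 for l in lines if l.startswith("S")) == 1
        assert sum(1 for l in lines if l.startswith("L")) == 0

    def test_branching_graph_links_carry_overlap(self, tmp_path):
        g = build_annotated_dbg({"a": ["ACGTA", "ACGTT"]}, 4, 3)
        path = tmp_path / "g.gfa"
        export_gfa(g, path)
        links = [l for l in path.read_text().splitlines() if l.startswith("L")]
        assert links and all(l.endswith("3M") for l in links)

    @pytest.mark.parametrize("seed", range(3))
    def test_round_trip_identity(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        g = build_annotated_dbg(
            {"a": [random_seq(rng, 70)], "b": [random_seq(rng, 50), random_seq(rng, 30)]},
            8, 5,
        )
        path = tmp_path / "g.gfa"
        export_gfa(g, path)
        g2 = import_gfa(path, seed_length=5)
        assert g2.k == g.k
        assert dict(g2.annotation) == dict(g.annotation)
        assert g2.label_sizes == g.label_sizes


class TestSerialization:
    def test_json_round_trip(self, tmp_path, linear_graph):
        g, _ = linear_graph
        path = tmp_path / "graph.json"
        g.to_json(path)
        g2 = AnnotatedDBG.from_json(path)
        assert g2.k == g.k and g2.seed_length == g.seed_length
        assert dict(g2.annotation) == dict(g.annotation)
        assert sorted(g2.covers) == sorted(g.covers)
        for label in g.covers:
            assert g2.covers[label].walks == g.covers[label].walks


def test_unitigs_partition_nodes():
    rng = np.random.default_rng(9)
    nodes = set()
    for _ in range(3):
        s = random_seq(rng, 40)
        nodes.update(s[i : i + 6] for i in range(35))
    unitigs = node_unitigs(nodes)
    seen = [v for u in unitigs for v in u]
    assert sorted(seen) == sorted(nodes)  # every node in exactly one unitig
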