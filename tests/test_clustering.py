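"""Similarity-graph construction, component clustering, proportional sampling."""

import numpy as np
import pytest

from repeatscape._kmers import kmer_set
from repeatscape.clustering import (
    build_graph,
    cluster_proportions,
    cluster_reads,
    extract_clusters,
    proportional_sample,
)


def random_read(rng, n=125):
    return np.frombuffer(b"ACGT", np.uint8)[rng.integers(0, 4, n)].tobytes().decode()


class TestProportionalSample:
    def test_genome_size_weighted_allocation(self):
        out = proportional_sample(
            {"fuc": list(range(5000)), "inc": list(range(6000))},
            {"fuc": 2.865, "inc": 3.52}, total_reads=10_000, seed=0,
        )
        assert (len(out["fuc"]), len(out["inc"])) == (4487, 5513)

    def test_equal_sizes_split_evenly(self):
        out = proportional_sample(
            {"a": list(range(600)), "b": list(range(600))},
            {"a": 1.0, "b": 1.0}, total_reads=1000, seed=0,
        )
        assert len(out["a"]) == len(out["b"]) == 500

    def test_same_seed_same_subsets(self):
        sets = {"a": list(range(500)), "b": list(range(700))}
        sizes = {"a": 1.3, "b": 2.1}
        assert proportional_sample(sets, sizes, 800, seed=42) == proportional_sample(
            sets, sizes, 800, seed=42
        )

    def test_allocations_sum_exactly(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            k = int(rng.integers(2, 6))
            sizes = {f"s{i}": float(rng.uniform(0.5, 5)) for i in range(k)}
            sets = {s: list(range(2000)) for s in sizes}
            total = int(rng.integers(10, 1500))
            out = proportional_sample(sets, sizes, total, seed=1)
            assert sum(len(v) for v in out.values()) == total

    def test_shortfall_names_species(self):
        with pytest.raises(ValueError, match="bigone"):
            proportional_sample(
                {"bigone": [1, 2], "small": list(range(100))},
                {"bigone": 10.0, "small": 1.0}, total_reads=50, seed=0,
            )


class TestBuildGraph:
    def test_identical_reads_edge_weight_one(self):
        rng = np.random.default_rng(0)
        r = random_read(rng)
        g = build_graph({"a": r, "b": r}, k=17, min_similarity=0.55)
        assert g.edges["a", "b"]["weight"] == 1.0

    def test_unrelated_reads_no_edge(self):
        rng = np.random.default_rng(1)
        g = build_graph({"a": random_read(rng), "b": random_read(rng)})
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 2

    def test_partial_overlap_against_direct_count(self):
        """Edge presence matches a directly counted shared-k-mer fraction."""
        rng = np.random.default_rng(2)
        core = random_read(rng, 80)  # ~64 shared 17-mers
        a = random_read(rng, 45) + core
        b = core + random_read(rng, 31)
        ka, kb = kmer_set(a, 17), kmer_set(b, 17)
        frac = np.intersect1d(ka, kb).size / min(ka.size, kb.size)
        assert 0.55 <= frac < 0.75  # constructed to sit above the threshold
        g = build_graph({"a": a, "b": b}, k=17, min_similarity=0.55)
        assert g.has_edge("a", "b")
        assert g.edges["a", "b"]["weight"] == pytest.approx(frac)

    def test_k_not_smaller_than_read_rejected(self):
        with pytest.raises(ValueError):
            build_graph({"a": "ACGTACGT", "b": "ACGTACGT"}, k=8)


class TestExtractClusters:
    def make_cliques(self, rng, sizes):
        """Disjoint read groups: members of a group are error-free copies."""
        reads, species_of = {}, {}
        for gi, size in enumerate(sizes):
            seq = random_read(rng)
            for i in range(size):
                rid = f"g{gi}_{i:03d}"
                reads[rid] = seq
                species_of[rid] = "sp"
        return reads, species_of

    def test_two_cliques_ranked_by_size(self):
        rng = np.random.default_rng(4)
        reads, species_of = self.make_cliques(rng, [30, 20, 3])
        g = build_graph(reads)
        clusters = extract_clusters(g, min_cluster_size=10, species_of=species_of)
        assert [c.size for c in clusters] == [30, 20]
        assert [c.cluster_id for c in clusters] == [1, 2]

    def test_empty_edge_set_no_clusters(self):
        rng = np.random.default_rng(5)
        reads = {f"r{i}": random_read(rng) for i in range(10)}
        assert extract_clusters(build_graph(reads), min_cluster_size=2) == []

    def test_rank_stable_under_relabeling(self):
        rng = np.random.default_rng(6)
        reads, species_of = self.make_cliques(rng, [12, 12, 5])
        ref = extract_clusters(build_graph(reads), 5, species_of)
        relabeled = {f"zz_{rid}": seq for rid, seq in reads.items()}
        sp2 = {f"zz_{rid}": "sp" for rid in species_of}
        out = extract_clusters(build_graph(relabeled), 5, sp2)
        assert [c.size for c in out] == [c.size for c in ref]
        # membership identical modulo the relabeling
        for a, b in zip(ref, out):
            assert {f"zz_{r}" for r in a.all_members()} == set(b.all_members())

    def test_union_find_path_matches_graph_path(self):
        """cluster_reads (capped union-find) equals build_graph + components."""
        rng = np.random.default_rng(7)
        reads, species_of = {}, {}
        for gi in range(4):
            base = random_read(rng, 400)
            for i in range(15):  # overlapping windows of a shared template
                s = int(rng.integers(0, 250))
                rid = f"f{gi}_{i:02d}"
                reads[rid] = base[s : s + 125]
                species_of[rid] = f"sp{i % 2}"
        for i in range(10):
            reads[f"bg{i}"] = random_read(rng)
            species_of[f"bg{i}"] = "sp0"
        via_graph = extract_clusters(build_graph(reads), 3, species_of)
        via_uf = cluster_reads(reads, species_of, min_cluster_size=3)
        assert [sorted(c.all_members()) for c in via_uf] == [
            sorted(c.all_members()) for c in via_graph
        ]


class TestClusterProportions:
    def test_share_of_analysed_reads(self):
        rng = np.random.default_rng(8)
        seq = random_read(rng)
        reads = {f"m{i}": seq for i in range(36)} | {f"p{i}": seq for i in range(5)}
        species_of = {r: ("fuc" if r.startswith("m") else "inc") for r in reads}
        clusters = cluster_reads(reads, species_of, min_cluster_size=2)
        cluster_proportions(clusters, {"fuc": 1000, "inc": 1000})
        assert clusters[0].proportion == {"fuc": 0.036, "inc": 0.005}

    def test_absent_species_gets_zero(self):
        rng = np.random.default_rng(9)
        seq = random_read(rng)
        reads = {f"m{i}": seq for i in range(10)}
        clusters = cluster_reads(reads, {r: "fuc" for r in reads}, min_cluster_size=2)
        cluster_proportions(clusters, {"fuc": 100, "inc": 50})
        assert clusters[0].proportion["inc"] == 0.0

    def test_zero_total_rejected(self):
        rng = np.random.default_rng(10)
        seq = random_read(rng)
        reads = {f"m{i}": seq for i in range(4)}
        clusters = cluster_reads(reads, {r: "fuc" for r in reads}, min_cluster_size=2)
        with pytest.raises(ValueError):
            cluster_proportions(clusters, {"fuc": 0})

    def test_proportions_sum_at_most_one(self):
        rng = np.random.default_rng(11)
        reads, species_of = {}, {}
        for gi in range(3):
            seq = random_read(rng)
            for i in range(10):
                rid = f"g{gi}_{i}"
                reads[rid] = seq
                species_of[rid] = "sp"
        clusters = cluster_reads(reads, species_of, min_cluster_size=2)
        cluster_proportions(clusters, {"sp": 30})
        assert sum(c.proportion["sp"] for c in clusters) <= 1.0 + 1e-12
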