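"""Similarity-graph read clustering and genome-proportional read sampling.

Reads from repetitive families co-occur at high copy number, so reads sharing
a large fraction of canonical k-mers are connected and the connected
components of that graph approximate repeat families. The share of a species'
analysed reads that falls into a cluster estimates the genome proportion of
the underlying family. For comparative runs across species, reads are first
sampled per species in proportion to genome size so that equal cluster shares
mean equal absolute genome amounts.

This is a deliberately simplified, desk-scale clustering: connected components
over an exact k-mer-similarity criterion, not a reimplementation of the
graph-layout clustering used by large repeat pipelines. Two entry points share
one contract: :func:`build_graph` + :func:`extract_clusters` materialize the
full graph (small inputs, exact), while :func:`cluster_reads` computes the
same components with a union-find and a per-k-mer candidate cap (large inputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from ._kmers import kmer_set, shared_fraction


@dataclass
class RepeatCluster:
    """A group of reads connected by similarity, with per-species bookkeeping.

    ``proportion`` is each species' cluster read count over that species' total
    analysed reads — the genome-proportion estimate for the repeat family.
    """

    cluster_id: int
    members: dict[str, list[str]]  # species -> member read ids
    counts: dict[str, int]
    proportion: dict[str, float] = field(default_factory=dict)
    annotation: str = "unclassified"
    annotation_tie: bool = False

    @property
    def size(self) -> int:
        return sum(self.counts.values())

    def all_members(self) -> list[str]:
        out: list[str] = []
        for ids in self.members.values():
            out.extend(ids)
        return out


def proportional_sample(
    read_sets: Mapping[str, Sequence],
    genome_sizes_1c: Mapping[str, float],
    total_reads: int,
    seed: int,
) -> dict[str, list]:
    """Sample reads per species proportionally to genome size.

    Species ``i`` receives ``total_reads * G_i / sum(G)`` reads (largest-
    remainder rounding so allocations sum exactly to ``total_reads``), drawn
    uniformly without replacement.
    """
    species = sorted(read_sets)
    missing = [s for s in species if s not in genome_sizes_1c]
    if missing:
        raise ValueError(f"no genome size for species: {missing}")
    sizes = np.array([genome_sizes_1c[s] for s in species], dtype=float)
    if (sizes <= 0).any():
        raise ValueError("all genome sizes must be positive")
    quota = total_reads * sizes / sizes.sum()
    alloc = np.floor(quota).astype(int)
    short = total_reads - int(alloc.sum())
    # distribute the rounding remainder to the largest fractional parts
    frac = quota - np.floor(quota)
    order = sorted(range(len(species)), key=lambda i: (-frac[i], species[i]))
    for i in order[:short]:
        alloc[i] += 1
    shortfalls = {
        s: (int(a), len(read_sets[s]))
        for s, a in zip(species, alloc)
        if a > len(read_sets[s])
    }
    if shortfalls:
        msg = "; ".join(
            f"{s}: need {need}, have {have}" for s, (need, have) in shortfalls.items()
        )
        raise ValueError(f"requested more reads than available — {msg}")
    rng = np.random.default_rng(seed)
    out: dict[str, list] = {}
    for s, a in zip(species, alloc):
        reads = read_sets[s]
        idx = np.sort(rng.choice(len(reads), size=int(a), replace=False))
        out[s] = [reads[i] for i in idx]
    return out


def build_graph(
    reads: Mapping[str, str],
    k: int = 17,
    min_similarity: float = 0.55,
) -> nx.Graph:
    """Exact read-similarity graph: edge iff shared canonical k-mer fraction
    (relative to the smaller read's k-mer profile) is >= ``min_similarity``.

    All reads appear as nodes; only pairs sharing at least one k-mer are
    evaluated (pairs sharing none have similarity 0 and cannot pass any
    positive threshold).
    """
    if len(reads) < 2:
        raise ValueError("need at least 2 reads to build a similarity graph")
    shortest = min(len(s) for s in reads.values())
    if k >= shortest:
        raise ValueError(f"k={k} must be smaller than the shortest read ({shortest} bp)")
    ids = list(reads)
    profiles = {rid: kmer_set(reads[rid], k) for rid in ids}
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    index: dict[int, list[str]] = {}
    for rid in ids:
        for code in profiles[rid].tolist():
            index.setdefault(code, []).append(rid)
    seen: set[tuple[str, str]] = set()
    for bucket in index.values():
        for i in range(len(bucket)):
            for j in range(i + 1, len(bucket)):
                key = (bucket[i], bucket[j])
                if key in seen:
                    continue
                seen.add(key)
                w = shared_fraction(profiles[key[0]], profiles[key[1]])
                if w >= min_similarity:
                    graph.add_edge(*key, weight=w)
    return graph


class _UnionFind:
    __slots__ = ("parent", "rank")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1


def _rank_components(
    components: list[list[str]],
    min_cluster_size: int,
    species_of: Mapping[str, str] | None,
) -> list[RepeatCluster]:
    """Filter components by size and rank them largest-first into clusters."""
    big = [sorted(c) for c in components if len(c) >= min_cluster_size]
    big.sort(key=lambda c: (-len(c), c[0]))
    clusters = []
    for rank, comp in enumerate(big, start=1):
        members: dict[str, list[str]] = {}
        for rid in comp:
            sp = species_of[rid] if species_of is not None else "all"
            members.setdefault(sp, []).append(rid)
        counts = {sp: len(ids) for sp, ids in members.items()}
        clusters.append(RepeatCluster(cluster_id=rank, members=members, counts=counts))
    return clusters


def extract_clusters(
    graph: nx.Graph,
    min_cluster_size: int = 2,
    species_of: Mapping[str, str] | None = None,
) -> list[RepeatCluster]:
    """Connected components of size >= ``min_cluster_size``, ranked by size.

    Smaller components count as singletons/small: excluded from cluster lists
    (and thus proportion numerators) but still part of analysed-read totals.
    Ties in size are broken by the smallest member read id, so ranking is
    stable under read relabeling.
    """
    components = [list(c) for c in nx.connected_components(graph)]
    return _rank_components(components, min_cluster_size, species_of)


def cluster_reads(
    reads: Mapping[str, str],
    species_of: Mapping[str, str] | None = None,
    k: int = 17,
    min_similarity: float = 0.55,
    min_cluster_size: int = 2,
    bucket_cap: int | None = 24,
) -> list[RepeatCluster]:
    """Scalable component clustering equivalent to build_graph + extract_clusters.

    A union-find replaces the explicit graph. For each read, candidate
    neighbours are drawn from the inverted k-mer index; ``bucket_cap`` bounds
    how many earlier reads per k-mer are considered (None = exact). Similarity
    is always computed exactly on the full k-mer profiles; candidates already
    in the read's component are skipped, which keeps dense repeat families
    cheap. K-mers occurring in only one read are never indexed (they cannot
    produce a candidate pair).
    """
    ids = list(reads)
    if len(ids) < 2:
        raise ValueError("need at least 2 reads")
    shortest = min(len(s) for s in reads.values())
    if k >= shortest:
        raise ValueError(f"k={k} must be smaller than the shortest read ({shortest} bp)")
    profiles = [kmer_set(reads[rid], k) for rid in ids]
    counts_all = np.unique(np.concatenate(profiles), return_counts=True)
    repeated = set(counts_all[0][counts_all[1] >= 2].tolist())
    uf = _UnionFind(len(ids))
    buckets: dict[int, list[int]] = {}
    for idx, prof in enumerate(profiles):
        cand: set[int] = set()
        for code in prof.tolist():
            if code not in repeated:
                continue
            bucket = buckets.get(code)
            if bucket is None:
                buckets[code] = [idx]
                continue
            cand.update(bucket if bucket_cap is None else bucket[:bucket_cap])
            bucket.append(idx)
        for j in cand:
            if uf.find(j) == uf.find(idx):
                continue
            if shared_fraction(prof, profiles[j]) >= min_similarity:
                uf.union(idx, j)
    groups: dict[int, list[str]] = {}
    for idx, rid in enumerate(ids):
        groups.setdefault(uf.find(idx), []).append(rid)
    return _rank_components(list(groups.values()), min_cluster_size, species_of)


def cluster_proportions(
    clusters: list[RepeatCluster],
    analysed_totals: Mapping[str, int],
) -> list[RepeatCluster]:
    """Fill each cluster's per-species proportion of all analysed reads.

    Every species in ``analysed_totals`` gets a proportion on every cluster
    (0 where the cluster has no reads of that species). Totals must cover the
    cluster sums — clusters are a partition of a subset of analysed reads.
    """
    for sp, total in analysed_totals.items():
        if total <= 0:
            raise ValueError(f"analysed total for {sp!r} must be positive")
        summed = sum(c.counts.get(sp, 0) for c in clusters)
        if summed > total:
            raise ValueError(
                f"{sp!r}: clusters hold {summed} reads but only {total} were analysed"
            )
    for c in clusters:
        unknown = set(c.counts) - set(analysed_totals)
        if unknown:
            raise ValueError(f"cluster {c.cluster_id}: no analysed total for {sorted(unknown)}")
        c.proportion = {
            sp: c.counts.get(sp, 0) / analysed_totals[sp] for sp in analysed_totals
        }
    return clusters
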