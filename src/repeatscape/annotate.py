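"""Repeat-lineage annotation of clusters and annotation transfer between runs.

Clusters are annotated by the majority of protein-domain (or ground-truth)
hits among their member reads. Clusters from a joint comparative run inherit
annotations from the per-species runs only under conservative thresholds: a
minimum fraction of member reads must carry a species-run annotation, the
unannotated share must dominate every competing label, and no two distinct
labels may both pass the annotated-fraction threshold (a majority conflict is
never overridden).

Lineages are slash-separated paths from class to family, e.g.
``LTR/Ty1-copia/SIRE-maximus`` or ``Tandem/MITE-like``; ``unclassified`` is a
terminal label never mixed with others.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .clustering import RepeatCluster

UNCLASSIFIED = "unclassified"

#: Closed lineage vocabulary (class -> family paths) used by the presets and
#: the taxonomy aggregation; extend freely for other study systems.
LINEAGE_VOCABULARY: tuple[str, ...] = (
    "LTR/Ty1-copia/SIRE-maximus",
    "LTR/Ty1-copia/Other",
    "LTR/Ty3-gypsy/Chromovirus/CRM",
    "LTR/Ty3-gypsy/Chromovirus/Tekay",
    "LTR/Ty3-gypsy/Chromovirus/Other",
    "LTR/Ty3-gypsy/Non-chromovirus/Athila",
    "LTR/Ty3-gypsy/Non-chromovirus/Retand",
    "LTR/Unclassified-LTR",
    "Non-LTR/LINE",
    "DNA/hAT",
    "DNA/MITE",
    "DNA/Other",
    "Tandem/rDNA",
    "Tandem/satDNA",
    "Tandem/MITE-like",
    UNCLASSIFIED,
)

#: Lineage classes counted as dispersed mobile elements ("Total TEs").
TE_CLASSES: tuple[str, ...] = ("LTR", "Non-LTR", "DNA")


def validate_lineage(path: str) -> str:
    if not path:
        raise ValueError("lineage path must be non-empty")
    parts = path.split("/")
    if UNCLASSIFIED in parts and len(parts) > 1:
        raise ValueError(f"{UNCLASSIFIED!r} is terminal and cannot be nested: {path!r}")
    return path


@dataclass
class DomainHitTable:
    """Read-level lineage hits from one source run (at most one per read)."""

    source: str
    hits: dict[str, str] = field(default_factory=dict)

    def add(self, read_id: str, lineage: str) -> None:
        lineage = validate_lineage(lineage)
        if read_id in self.hits and self.hits[read_id] != lineage:
            raise ValueError(
                f"read {read_id!r} already has hit {self.hits[read_id]!r} in {self.source!r}"
            )
        self.hits[read_id] = lineage

    def get(self, read_id: str) -> str | None:
        return self.hits.get(read_id)


def merge_hit_tables(tables: Iterable[DomainHitTable]) -> dict[str, str]:
    """Combine per-run hit tables into one read -> lineage lookup."""
    merged: dict[str, str] = {}
    for t in tables:
        merged.update(t.hits)
    return merged


def _label_counts(cluster: RepeatCluster, hits: Mapping[str, str]) -> tuple[Counter, int]:
    members = cluster.all_members()
    counts = Counter(hits[r] for r in members if hits.get(r) is not None)
    return counts, len(members)


def annotate_majority(
    cluster: RepeatCluster,
    hits: DomainHitTable | Mapping[str, str],
) -> str:
    """Annotate a cluster with the most frequent hit label among member reads.

    Exact ties are broken to the lexicographically smallest lineage path and
    flagged on the cluster (``annotation_tie``). A cluster without any hit is
    ``unclassified``. The cluster is updated in place and the lineage returned.
    """
    lookup = hits.hits if isinstance(hits, DomainHitTable) else hits
    counts, n = _label_counts(cluster, lookup)
    if n == 0:
        raise ValueError(f"cluster {cluster.cluster_id} is empty")
    if not counts:
        cluster.annotation, cluster.annotation_tie = UNCLASSIFIED, False
        return UNCLASSIFIED
    best = max(counts.values())
    winners = sorted(l for l, c in counts.items() if c == best)
    cluster.annotation = winners[0]
    cluster.annotation_tie = len(winners) > 1
    return cluster.annotation


def transfer_annotation(
    comp_cluster: RepeatCluster,
    species_annotations: Iterable[DomainHitTable] | Mapping[str, str],
    min_annotated_frac: float = 0.20,
    max_second_unclassified_frac: float = 0.50,
) -> str:
    """Transfer a species-run annotation to a comparative-run cluster.

    The candidate is the majority label among member reads annotated in the
    species runs. It is transferred iff (i) at least ``min_annotated_frac`` of
    member reads carry any species-run annotation, (ii) the unannotated share
    exceeds ``max_second_unclassified_frac`` (so "unclassified" is the only
    category competing with the candidate), and (iii) no other label also
    reaches ``min_annotated_frac`` — a majority conflict between two labels is
    never overridden. Otherwise the cluster stays unclassified.
    """
    if isinstance(species_annotations, Mapping):
        lookup = dict(species_annotations)
    else:
        lookup = merge_hit_tables(species_annotations)
    counts, n = _label_counts(comp_cluster, lookup)
    if n == 0:
        raise ValueError(f"cluster {comp_cluster.cluster_id} is empty")
    annotated = sum(counts.values())
    f = annotated / n
    unclassified_frac = 1 - f
    competing = [l for l, c in counts.items() if c / n >= min_annotated_frac]
    if (
        f >= min_annotated_frac
        and unclassified_frac > max_second_unclassified_frac
        and len(competing) <= 1
        and counts
    ):
        best = max(counts.values())
        winners = sorted(l for l, c in counts.items() if c == best)
        comp_cluster.annotation = winners[0]
        comp_cluster.annotation_tie = len(winners) > 1
    else:
        comp_cluster.annotation, comp_cluster.annotation_tie = UNCLASSIFIED, False
    return comp_cluster.annotation


def aggregate_taxonomy(clusters: list[RepeatCluster]) -> pd.DataFrame:
    """Per-species genome proportions summed over the lineage hierarchy.

    Every prefix of every cluster lineage becomes a row (so ``LTR/Ty1-copia``
    is the sum of its families), plus two summary rows: ``Total TEs`` (the
    dispersed mobile-element classes) and ``Total repeats`` (every cluster,
    including tandem repeats and unclassified).
    """
    species = sorted({sp for c in clusters for sp in c.proportion})
    if not species:
        raise ValueError("clusters carry no proportions; run cluster_proportions first")
    prefixes: set[str] = set()
    for c in clusters:
        parts = c.annotation.split("/")
        prefixes.update("/".join(parts[: i + 1]) for i in range(len(parts)))
    rows = sorted(prefixes) + ["Total TEs", "Total repeats"]
    table = pd.DataFrame(0.0, index=rows, columns=species)
    for c in clusters:
        parts = c.annotation.split("/")
        nodes = ["/".join(parts[: i + 1]) for i in range(len(parts))]
        nodes.append("Total repeats")
        if parts[0] in TE_CLASSES:
            nodes.append("Total TEs")
        for sp in species:
            p = c.proportion.get(sp, 0.0)
            for node in nodes:
                table.loc[node, sp] += p
    table.index.name = "lineage"
    return table


# ---------------------------------------------------------------------------
# Tabular interchange

def read_hits_tsv(path) -> list[DomainHitTable]:
    """Read a hits table TSV (read_id, source_run, lineage) into per-run tables."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    tables = []
    for source, grp in df.groupby("source_run", sort=True):
        t = DomainHitTable(source=str(source))
        for _, row in grp.iterrows():
            t.add(row["read_id"], row["lineage"])
        tables.append(t)
    return tables


def write_hits_tsv(tables: Iterable[DomainHitTable], path) -> None:
    rows = [
        {"read_id": rid, "source_run": t.source, "lineage": lin}
        for t in tables
        for rid, lin in sorted(t.hits.items())
    ]
    pd.DataFrame(rows, columns=["read_id", "source_run", "lineage"]).to_csv(
        path, sep="\t", index=False
    )
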