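"""End-to-end synthetic comparative runs: simulate -> preprocess -> cluster ->
annotate -> compare, with ground-truth evaluation helpers.

This is the orchestration layer the analysis drivers and the acceptance checks
use. Genome sizes for read allocation and the in-silico expectation are taken
from the simulated genome lengths (the simulator's analogue of flow-cytometry
sizes); read pairs enter the similarity graph as independent mates carrying
their pair id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import transfer_annotation
from .clustering import (
    RepeatCluster,
    cluster_proportions,
    cluster_reads,
    proportional_sample,
)
from .comparative import BiasRecord, build_comparative_table, flag_deviating_clusters
from .preprocess import OrganelleIndex, preprocess_pairs
from .simdata import (
    PRESET_AMPLIFICATIONS,
    SINGLE_COPY,
    Genome,
    SimulationConfig,
    preset_lineages,
    preset_parent_specs,
    random_organelle,
    simulate_allopolyploid,
    simulate_parents,
    simulate_reads,
)

MATERNAL = "maternal"
PATERNAL = "paternal"


@dataclass
class PipelineResult:
    """Everything a synthetic comparative run produced, plus the ground truth."""

    genomes: dict[str, Genome]
    analysed_totals: dict[str, int]
    clusters: list[RepeatCluster]
    table: pd.DataFrame
    records: list[BiasRecord]
    mate_truth: dict[str, str]  # mate id -> true family (or single-copy/organelle)
    true_fractions: pd.DataFrame  # family x species, genome base-pair fractions
    preprocess_logs: dict[str, dict]
    cluster_family: dict[int, str] = field(default_factory=dict)
    cluster_purity: dict[int, float] = field(default_factory=dict)

    @property
    def polyploids(self) -> list[str]:
        return [sp for sp in self.genomes if sp not in (MATERNAL, PATERNAL)]

    def family_proportions(self) -> pd.DataFrame:
        """Estimated per-family proportions: clusters aggregated by their
        dominant ground-truth family, against the true genome fractions."""
        species = list(self.genomes)
        est = pd.DataFrame(0.0, index=self.true_fractions.index, columns=species)
        for c in self.clusters:
            fam = self.cluster_family.get(c.cluster_id)
            if fam in est.index:
                for sp in species:
                    est.loc[fam, sp] += c.proportion.get(sp, 0.0)
        return est

    def retention_truth(self, threshold: float = 0.20) -> pd.DataFrame:
        """Ground-truth retention analysis per (family, polyploid).

        For each family and polyploid: the true relative deviation from the
        in-silico expectation (computed from the simulated base-pair
        fractions, so it includes the dilution a polyploid's own amplified
        families impose on everything else), the sampling SD of the measured
        deviation at the realized read-pair counts, whether the truth exceeds
        the threshold, and whether that call is decidable (the truth sits
        more than 3 SD from the threshold).
        """
        true = self.true_fractions
        g_m = self.genomes[MATERNAL].length
        g_p = self.genomes[PATERNAL].length
        rows = []
        for fam in true.index:
            p_m, p_p = true.loc[fam, MATERNAL], true.loc[fam, PATERNAL]
            e_t = (p_m * g_m + p_p * g_p) / (g_m + g_p)
            n_m = self.analysed_totals[MATERNAL] / 2
            n_p = self.analysed_totals[PATERNAL] / 2
            w_m, w_p = g_m / (g_m + g_p), g_p / (g_m + g_p)
            var_e = w_m**2 * p_m * (1 - p_m) / n_m + w_p**2 * p_p * (1 - p_p) / n_p
            for poly in self.polyploids:
                o_t = true.loc[fam, poly]
                n_q = self.analysed_totals[poly] / 2
                var_o = o_t * (1 - o_t) / n_q
                if o_t == 0 or e_t == 0:
                    continue
                dev = o_t / e_t - 1
                sd = (o_t / e_t) * np.sqrt(var_o / o_t**2 + var_e / e_t**2)
                rows.append(
                    {
                        "family": fam,
                        "polyploid": poly,
                        "true_deviation": dev,
                        "sd": sd,
                        "exceeds": abs(dev) > threshold,
                        "decidable": abs(abs(dev) - threshold) > 3 * sd,
                    }
                )
        return pd.DataFrame(rows)

    def expected_retained(self, threshold: float = 0.20) -> dict[str, bool | None]:
        """Per family: the retention flag implied by the ground truth, or None
        when sampling noise makes the flag undecidable at this depth (the true
        deviation of some polyploid lies within 3 SD of the threshold and no
        decidable polyploid already exceeds it)."""
        rt = self.retention_truth(threshold)
        out: dict[str, bool | None] = {}
        for fam, grp in rt.groupby("family"):
            if ((grp["exceeds"]) & (grp["decidable"])).any():
                out[fam] = True
            elif grp["decidable"].all() and not grp["exceeds"].any():
                out[fam] = False
            else:
                out[fam] = None
        return out

    def family_records(self) -> dict[str, BiasRecord]:
        """The bias record of each family's dominant cluster (largest wins)."""
        by_cluster = {r.cluster_id: r for r in self.records}
        out: dict[str, BiasRecord] = {}
        for c in self.clusters:  # clusters are ranked largest-first
            fam = self.cluster_family.get(c.cluster_id)
            if fam and fam != SINGLE_COPY and fam not in out and c.cluster_id in by_cluster:
                out[fam] = by_cluster[c.cluster_id]
        return out


def _dominant_family(cluster: RepeatCluster, mate_truth: dict[str, str]) -> tuple[str, float]:
    counts: dict[str, int] = {}
    members = cluster.all_members()
    for rid in members:
        fam = mate_truth.get(rid, SINGLE_COPY)
        counts[fam] = counts.get(fam, 0) + 1
    fam = max(sorted(counts), key=counts.get)
    return fam, counts[fam] / len(members)


def run_synthetic_pipeline(
    seed: int,
    total_read_pairs: int = 80_000,
    polyploid_presets: tuple[str, ...] = ("young", "intermediate", "triple_mite"),
    config: SimulationConfig | None = None,
    hit_rate: float = 0.30,
    min_similarity: float = 0.55,
    k: int = 17,
    min_proportion: float = 0.001,
    deviation_threshold: float = 0.20,
    origin_threshold: float = 0.20,
) -> PipelineResult:
    """One full comparative experiment on the study-system-like preset.

    ``total_read_pairs`` is the comparative-run depth (pairs across all
    species, allocated proportionally to genome size); each genome is simulated
    with a 30% read surplus so the allocation is always satisfiable after
    preprocessing losses.
    """
    if config is None:
        config = SimulationConfig(seed=seed, organelle_fraction=0.02)
    m_specs, p_specs, m_back, p_back = preset_parent_specs(seed)
    maternal, paternal = simulate_parents(
        m_specs, p_specs, config, m_back, p_back,
        maternal_name=MATERNAL, paternal_name=PATERNAL,
    )
    genomes: dict[str, Genome] = {MATERNAL: maternal, PATERNAL: paternal}
    for preset in polyploid_presets:
        genomes[f"poly_{preset}"] = simulate_allopolyploid(
            maternal, paternal, PRESET_AMPLIFICATIONS[preset], config,
            name=f"poly_{preset}",
        )
    sizes = {sp: float(g.length) for sp, g in genomes.items()}
    total_size = sum(sizes.values())
    organelle_seq = random_organelle(config)
    organelle_index = OrganelleIndex.from_sequence(organelle_seq, k=31)

    reads: dict[str, dict[str, str]] = {}
    mate_truth: dict[str, str] = {}
    logs: dict[str, dict] = {}
    for sp, genome in genomes.items():
        want_pairs = math.ceil(total_read_pairs * sizes[sp] / total_size * 1.3) + 50
        pairs, truth = simulate_reads(
            genome, config, n_pairs=want_pairs, organelle_seq=organelle_seq
        )
        kept, log = preprocess_pairs(pairs, organelle=organelle_index, trim_length=125)
        logs[sp] = log
        pool: dict[str, str] = {}
        for p in kept:
            pool[f"{p.id}/1"] = p.seq1
            pool[f"{p.id}/2"] = p.seq2
        reads[sp] = pool
        for row in truth.itertuples():
            mate_truth[f"{row.pair_id}/1"] = row.family_1
            mate_truth[f"{row.pair_id}/2"] = row.family_2

    sampled = proportional_sample(
        {sp: sorted(pool) for sp, pool in reads.items()},
        sizes, total_reads=2 * total_read_pairs, seed=seed,
    )
    analysed: dict[str, str] = {}
    species_of: dict[str, str] = {}
    for sp, ids in sampled.items():
        for rid in ids:
            analysed[rid] = reads[sp][rid]
            species_of[rid] = sp
    analysed_totals = {sp: len(ids) for sp, ids in sampled.items()}

    min_cluster_size = max(2, round(0.00005 * len(analysed)))
    clusters = cluster_reads(
        analysed, species_of, k=k, min_similarity=min_similarity,
        min_cluster_size=min_cluster_size,
    )
    cluster_proportions(clusters, analysed_totals)

    lineages = preset_lineages()
    merged_hits = _truth_hits_for(analysed, mate_truth, lineages, hit_rate, seed)
    for c in clusters:
        transfer_annotation(c, merged_hits)

    table = build_comparative_table(
        clusters, MATERNAL, PATERNAL,
        polyploids=[sp for sp in genomes if sp not in (MATERNAL, PATERNAL)],
        genome_sizes_1c=sizes,
    )
    records = flag_deviating_clusters(
        table,
        min_proportion=min_proportion,
        deviation_threshold=deviation_threshold,
        origin_threshold=origin_threshold,
    )

    true_fractions = pd.DataFrame(
        {sp: pd.Series(g.family_fractions()) for sp, g in genomes.items()}
    ).fillna(0.0)
    result = PipelineResult(
        genomes=genomes,
        analysed_totals=analysed_totals,
        clusters=clusters,
        table=table,
        records=records,
        mate_truth=mate_truth,
        true_fractions=true_fractions,
        preprocess_logs=logs,
    )
    for c in clusters:
        fam, purity = _dominant_family(c, mate_truth)
        result.cluster_family[c.cluster_id] = fam
        result.cluster_purity[c.cluster_id] = purity
    return result


def _truth_hits_for(
    analysed: dict[str, str],
    mate_truth: dict[str, str],
    lineages: dict[str, str],
    hit_rate: float,
    seed: int,
) -> dict[str, str]:
    """Ground-truth domain hits for the analysed mates (stand-in for the
    per-species annotation runs): each repeat-origin mate carries its family's
    lineage with probability ``hit_rate``."""
    import numpy as np

    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    out: dict[str, str] = {}
    for rid in sorted(analysed):
        fam = mate_truth.get(rid, SINGLE_COPY)
        if fam in lineages and rng.random() < hit_rate:
            out[rid] = lineages[fam]
    return out
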