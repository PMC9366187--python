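"""Comparative allopolyploid repeat math: additivity expectations and deviations.

The additive null for an allopolyploid is the "in silico" parent mixture: each
cluster's expected proportion is the genome-size-weighted mean of the two
parental proportions (a comparative run samples reads proportionally to genome
size, so read pools mix in exactly these weights). Observed polyploid
proportions are compared against this null three ways:

* a normalized deviation in [-1, 1], zero at additivity, -1 at total loss —
  realized as (obs - exp) / max(obs, exp), which is antisymmetric;
* a parental-origin class per cluster (maternal-larger / paternal-larger /
  similar) from the relative difference between the parental proportions;
* a retention flag marking clusters where at least one polyploid departs from
  the expectation by more than a threshold relative difference.

Proportions are converted to absolute genome amounts (Gbp) by multiplying with
the genome size at an explicit basis (monoploid 1C or holoploid 2C), which
reproduces the net-amount arithmetic of the study: totals per parent, the
MITE-like amounts, and maximum pairwise differences among the polyploids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import RepeatCluster
from .genomesize import SpeciesSizeSummary, relative_difference

MATERNAL_LARGER = "maternal-larger"
PATERNAL_LARGER = "paternal-larger"
SIMILAR = "similar"


@dataclass(frozen=True)
class BiasRecord:
    """Per-cluster parental-origin class, per-polyploid deviation, retention flag."""

    cluster_id: int
    lineage: str
    parental_origin: str
    deviation: dict[str, float] = field(default_factory=dict)
    retained: bool = False


def in_silico_expectation(
    p_maternal: float, p_paternal: float, g_maternal_1c: float, g_paternal_1c: float
) -> float:
    """Expected additive proportion: genome-size-weighted mean of the parents."""
    if g_maternal_1c <= 0 or g_paternal_1c <= 0:
        raise ValueError("parental genome sizes must be positive")
    return (p_maternal * g_maternal_1c + p_paternal * g_paternal_1c) / (
        g_maternal_1c + g_paternal_1c
    )


def normalized_deviation(observed: float, expected: float) -> float:
    """(obs - exp) / max(obs, exp): in [-1, 1], 0 at additivity, antisymmetric.

    -1 means total loss of the cluster, +1 appearance from nothing; both zero
    is the degenerate no-signal case and maps to 0.
    """
    if observed < 0 or expected < 0:
        raise ValueError("proportions must be non-negative")
    if observed == 0 and expected == 0:
        return 0.0
    return (observed - expected) / max(observed, expected)


def log2_deviation(observed: float, expected: float) -> float:
    """Alternative deviation scale: log2(obs/exp); infinite at either boundary."""
    if observed < 0 or expected < 0:
        raise ValueError("proportions must be non-negative")
    if observed == 0 and expected == 0:
        return 0.0
    with np.errstate(divide="ignore"):
        return float(np.log2(observed) - np.log2(expected))


def classify_parental_origin(
    p_maternal: float, p_paternal: float, threshold: float = 0.20
) -> str:
    """Origin class from the parental proportions alone.

    The cluster is assigned to the larger parent iff the relative difference
    (baseline: the larger proportion) is >= ``threshold`` (boundary inclusive);
    otherwise it is "similar".
    """
    if p_maternal < 0 or p_paternal < 0:
        raise ValueError("proportions must be non-negative")
    if p_maternal == 0 and p_paternal == 0:
        raise ValueError("cluster absent from both parents cannot be classified")
    diff = abs(p_maternal - p_paternal) / max(p_maternal, p_paternal)
    if diff >= threshold:
        return MATERNAL_LARGER if p_maternal > p_paternal else PATERNAL_LARGER
    return SIMILAR


def build_comparative_table(
    clusters: list[RepeatCluster],
    maternal: str,
    paternal: str,
    polyploids: list[str],
    genome_sizes_1c: dict[str, float],
) -> pd.DataFrame:
    """Clusters x species proportion matrix with lineage and in_silico columns."""
    species = [maternal, paternal, *polyploids]
    rows = []
    for c in clusters:
        if not c.proportion:
            raise ValueError(f"cluster {c.cluster_id} has no proportions")
        row = {"cluster_id": c.cluster_id, "lineage": c.annotation}
        for sp in species:
            row[sp] = c.proportion.get(sp, 0.0)
        row["in_silico"] = in_silico_expectation(
            row[maternal], row[paternal],
            genome_sizes_1c[maternal], genome_sizes_1c[paternal],
        )
        rows.append(row)
    table = pd.DataFrame(rows).set_index("cluster_id")
    table.attrs.update(maternal=maternal, paternal=paternal, polyploids=list(polyploids))
    return table


def read_comparative_table(
    path,
    maternal: str,
    paternal: str,
    polyploids: list[str],
) -> pd.DataFrame:
    """Ingest an externally produced comparative cluster table (TSV).

    Expected columns: cluster_id, lineage, one proportion column per species,
    and optionally in_silico (recomputed from parental proportions and the
    table's genome sizes is the caller's job if absent).
    """
    table = pd.read_csv(path, sep="\t").set_index("cluster_id")
    missing = [c for c in (maternal, paternal, *polyploids) if c not in table.columns]
    if missing:
        raise ValueError(f"cluster table lacks species columns: {missing}")
    table.attrs.update(maternal=maternal, paternal=paternal, polyploids=list(polyploids))
    return table


def flag_deviating_clusters(
    table: pd.DataFrame,
    min_proportion: float = 0.001,
    deviation_threshold: float = 0.20,
    origin_threshold: float = 0.20,
    min_proportion_mode: str = "all",
) -> list[BiasRecord]:
    """Size-filter clusters, classify parental origin, and flag deviators.

    Clusters below ``min_proportion`` in every species (mode "all", default;
    mode "any" drops on any sub-threshold species) are removed before
    classification. A survivor is ``retained`` iff at least one polyploid's
    relative difference to the in-silico expectation strictly exceeds
    ``deviation_threshold`` (a zero expectation with non-zero observation
    counts as an exceedance). Per-polyploid normalized deviations are reported
    for every survivor.
    """
    if "in_silico" not in table.columns:
        raise ValueError("comparative table lacks the in_silico column")
    maternal = table.attrs["maternal"]
    paternal = table.attrs["paternal"]
    polyploids = table.attrs["polyploids"]
    species = [maternal, paternal, *polyploids]
    if min_proportion_mode not in ("all", "any"):
        raise ValueError(f"unknown min_proportion_mode {min_proportion_mode!r}")
    records: list[BiasRecord] = []
    for cid, row in table.iterrows():
        props = [row[sp] for sp in species]
        if min_proportion_mode == "all":
            if all(p < min_proportion for p in props):
                continue
        else:
            if any(p < min_proportion for p in props):
                continue
        origin = classify_parental_origin(
            row[maternal], row[paternal], threshold=origin_threshold
        )
        expected = row["in_silico"]
        deviations = {}
        retained = False
        for poly in polyploids:
            obs = row[poly]
            deviations[poly] = normalized_deviation(obs, expected)
            if expected > 0:
                if abs(obs - expected) / expected > deviation_threshold:
                    retained = True
            elif obs > 0:
                retained = True
        records.append(
            BiasRecord(
                cluster_id=cid,
                lineage=row.get("lineage", "unclassified"),
                parental_origin=origin,
                deviation=deviations,
                retained=retained,
            )
        )
    return records


def bias_records_to_frame(records: list[BiasRecord]) -> pd.DataFrame:
    """Bias records as a flat table (one deviation column per polyploid)."""
    polyploids = sorted({p for r in records for p in r.deviation})
    rows = []
    for r in records:
        row = {
            "cluster_id": r.cluster_id,
            "lineage": r.lineage,
            "parental_origin": r.parental_origin,
            "retained": r.retained,
        }
        for p in polyploids:
            row[f"deviation_{p}"] = r.deviation.get(p, np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster_id")


def proportions_to_amounts(proportion: float, genome_size_gbp: float) -> float:
    """Genome amount (Gbp) of a repeat at a stated genome-size basis.

    ``genome_size_gbp`` must already be on the intended basis (1C for
    monoploid/"haploid" amounts, 2C for holoploid amounts); the caller carries
    the basis label.
    """
    if proportion < 0 or genome_size_gbp < 0:
        raise ValueError("inputs must be non-negative")
    return proportion * genome_size_gbp


def abundance_table(
    proportions: pd.DataFrame,
    summaries: dict[str, SpeciesSizeSummary],
    basis: str = "monoploid-1C",
) -> pd.DataFrame:
    """Scale a lineage (or cluster) x species proportion table to Gbp amounts."""
    if basis not in ("monoploid-1C", "holoploid-2C"):
        raise ValueError(f"unknown basis {basis!r}")
    missing = [sp for sp in proportions.columns if sp not in summaries]
    if missing:
        raise ValueError(f"no genome-size summary for species: {missing}")
    sizes = {
        sp: (summaries[sp].size_2c_gbp if basis == "holoploid-2C"
             else summaries[sp].size_2c_gbp / 2)
        for sp in proportions.columns
    }
    out = proportions.mul(pd.Series(sizes), axis=1)
    out.attrs.update(basis=basis, units="Gbp")
    return out


def additivity_report(
    proportions: pd.DataFrame,
    summaries: dict[str, SpeciesSizeSummary],
    maternal: str,
    paternal: str,
    polyploids: list[str],
) -> dict[str, pd.DataFrame | pd.Series]:
    """Net-amount arithmetic coupling genome sizes with repeat proportions.

    From a lineage x species proportion table and per-species genome sizes,
    derive: absolute amounts on both bases, the in-silico expected proportion
    per lineage, each polyploid's net and relative departure from the expected
    2C amount (expected amount = in-silico proportion x additive 2C size), and
    the maximum pairwise 2C amount difference among the polyploids.
    """
    species = [maternal, paternal, *polyploids]
    missing = [sp for sp in species if sp not in proportions.columns]
    if missing:
        raise ValueError(f"species missing from proportion table: {missing}")
    missing = [sp for sp in species if sp not in summaries]
    if missing:
        raise ValueError(f"species missing from genome-size summaries: {missing}")
    props = proportions[species]
    amounts_1c = abundance_table(props, summaries, basis="monoploid-1C")
    amounts_2c = abundance_table(props, summaries, basis="holoploid-2C")
    g_m = summaries[maternal].size_2c_gbp / 2
    g_p = summaries[paternal].size_2c_gbp / 2
    expected_prop = (props[maternal] * g_m + props[paternal] * g_p) / (g_m + g_p)
    # additive holoploid size of a tetraploid: one full 2C complement per parent
    additive_2c = summaries[maternal].size_2c_gbp + summaries[paternal].size_2c_gbp
    expected_amount_2c = expected_prop * additive_2c
    net_departure = amounts_2c[polyploids].sub(expected_amount_2c, axis=0)
    rel_departure = net_departure.div(expected_amount_2c.replace(0, np.nan), axis=0)
    diffs = {}
    pairs = {}
    for lineage in props.index:
        vals = amounts_2c.loc[lineage, polyploids]
        hi, lo = vals.idxmax(), vals.idxmin()
        diffs[lineage] = float(vals[hi] - vals[lo])
        pairs[lineage] = f"{hi} vs {lo}"
    return {
        "amounts_1c_gbp": amounts_1c,
        "amounts_2c_gbp": amounts_2c,
        "in_silico_proportion": expected_prop,
        "expected_amount_2c_gbp": expected_amount_2c,
        "net_departure_2c_gbp": net_departure,
        "relative_departure": rel_departure,
        "max_polyploid_diff_2c_gbp": pd.Series(diffs),
        "max_polyploid_diff_pair": pd.Series(pairs),
    }


def parental_size_difference(summaries: dict[str, SpeciesSizeSummary],
                             maternal: str, paternal: str) -> float:
    """Relative 1C genome-size difference between the parents (smaller baseline)."""
    return relative_difference(
        summaries[maternal].mean_1c_pg, summaries[paternal].mean_1c_pg,
        baseline="smaller",
    )
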