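"""Parental-origin and deviation classification of the published lineage table.

Treats each lineage row of the published proportion table as a cluster:
classifies it as originally larger in the maternal or paternal diploid (>= 20%
relative difference) or similar, computes each allotetraploid's normalized
deviation from the in-silico additive expectation, and flags lineages where
any polyploid departs from additivity by more than 20%.

Writes results/parental_bias.tsv.

Usage: python analysis/04_parental_bias.py [--out results]
"""

import argparse
from pathlib import Path

from repeatscape.comparative import bias_records_to_frame, flag_deviating_clusters
from repeatscape.reference import (
    MATERNAL,
    PATERNAL,
    POLYPLOIDS,
    REPEAT_PROPORTIONS_PCT,
    repeat_proportions,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    props = repeat_proportions()
    leaves = REPEAT_PROPORTIONS_PCT["lineage"].notna()
    table = props[leaves].copy()
    table["lineage"] = REPEAT_PROPORTIONS_PCT.loc[leaves, "lineage"]
    from repeatscape.reference import GENOME_SIZES

    g = GENOME_SIZES["mean_1c_pg"]
    table["in_silico"] = (
        table[MATERNAL] * g[MATERNAL] + table[PATERNAL] * g[PATERNAL]
    ) / (g[MATERNAL] + g[PATERNAL])
    table.index.name = "cluster_id"
    table.attrs.update(maternal=MATERNAL, paternal=PATERNAL, polyploids=list(POLYPLOIDS))

    records = flag_deviating_clusters(table)
    frame = bias_records_to_frame(records)
    frame.to_csv(args.out / "parental_bias.tsv", sep="\t")

    print("Lineage-level parental bias against the in-silico allopolyploid:")
    print(frame.round(3).to_string())
    retained = frame[frame["retained"]]
    print(f"\n{len(retained)} lineages exceed the ±20% deviation threshold:")
    print(", ".join(retained["lineage"]))


if __name__ == "__main__":
    main()
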