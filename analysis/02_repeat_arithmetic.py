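"""Net repeat amounts from the published genome sizes and proportion table.

Feeds the flow-cytometry 2C sizes and the repeat genome-proportion table
through the comparative module: absolute amounts per lineage and species on
both bases (monoploid 1C, holoploid 2C), the in-silico additive expectation
per lineage, each polyploid's departure from the expected amount, and the
maximum pairwise differences among the allotetraploids.

Writes results/amounts_1c_gbp.csv, results/amounts_2c_gbp.csv,
results/additivity_report.csv.

Usage: python analysis/02_repeat_arithmetic.py [--out results]
"""

import argparse
from pathlib import Path

import pandas as pd

from repeatscape.comparative import additivity_report, parental_size_difference
from repeatscape.reference import POLYPLOIDS, genome_size_summaries, repeat_proportions


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    summaries = genome_size_summaries()
    props = repeat_proportions()
    rep = additivity_report(props, summaries, "fuc", "inc", list(POLYPLOIDS))

    a1, a2 = rep["amounts_1c_gbp"], rep["amounts_2c_gbp"]
    a1.round(4).to_csv(args.out / "amounts_1c_gbp.csv")
    a2.round(4).to_csv(args.out / "amounts_2c_gbp.csv")
    combined = pd.DataFrame(
        {
            "in_silico_proportion": rep["in_silico_proportion"],
            "expected_amount_2c_gbp": rep["expected_amount_2c_gbp"],
            "max_polyploid_diff_2c_gbp": rep["max_polyploid_diff_2c_gbp"],
            "max_polyploid_diff_pair": rep["max_polyploid_diff_pair"],
        }
    )
    combined.round(4).to_csv(args.out / "additivity_report.csv")

    print("Parental totals, 1C basis (Gbp):")
    print(a1.loc[["Total repeats", "LTR retrotransposons"], ["fuc", "inc"]].round(2))
    print("\nMITE-like, 2C basis (Mbp):")
    print((a2.loc["MITE-like", ["fuc", "inc"]] * 1000).round(1))
    print(
        f"\nIn-silico total-repeat expectation: "
        f"{rep['in_silico_proportion']['Total repeats'] * 100:.1f}%"
    )
    print(
        "Max total-repeat difference among polyploids: "
        f"{rep['max_polyploid_diff_2c_gbp']['Total repeats']:.2f} Gbp "
        f"({rep['max_polyploid_diff_pair']['Total repeats']})"
    )
    print(
        "Max tandem-repeat difference among polyploids: "
        f"{rep['max_polyploid_diff_2c_gbp']['Tandem repeats'] * 1000:.0f} Mbp"
    )
    print(
        "Diploid 1C genome-size difference: "
        f"{parental_size_difference(summaries, 'fuc', 'inc') * 100:.1f}%"
    )


if __name__ == "__main__":
    main()
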