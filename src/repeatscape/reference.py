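"""Published reference values for the marsh-orchid study system.

Flow-cytometry genome sizes and repeat genome-proportion estimates for the two
diploid parents (Dactylorhiza fuchsii "fuc", maternal; D. incarnata "inc",
paternal) and their five sibling allotetraploids (pur, bal, pra, tra, maj,
ordered young to old). Cluster-level read data are not included — the
proportion table is the fixed input to the comparative arithmetic, exactly as
a comparative clustering run would supply it.
"""

from __future__ import annotations

import pandas as pd

from .genomesize import SpeciesSizeSummary, picograms_to_gigabases

MATERNAL = "fuc"
PATERNAL = "inc"
POLYPLOIDS = ("pur", "bal", "pra", "tra", "maj")  # young -> old
SPECIES = (MATERNAL, PATERNAL, *POLYPLOIDS)

#: Flow-cytometry summary: sample count, mean 1C (pg), SEM (pg), printed 2C (Gbp).
GENOME_SIZES = pd.DataFrame(
    {
        "ploidy": [2, 2, 4, 4, 4, 4, 4],
        "n": [4, 7, 5, 7, 5, 5, 8],
        "mean_1c_pg": [2.93, 3.60, 6.69, 6.83, 7.40, 7.24, 7.28],
        "sem_1c_pg": [0.18, 0.14, 0.05, 0.03, 0.29, 0.25, 0.16],
        "size_2c_gbp": [5.73, 7.04, 13.09, 13.37, 14.47, 14.16, 14.24],
    },
    index=pd.Index(SPECIES, name="species"),
)

#: Repeat genome proportions (%), lineage rows x species columns. Leaf rows
#: carry a lineage path; aggregate rows (e.g. "Ty1-copia") are printed sums.
REPEAT_PROPORTIONS_PCT = pd.DataFrame(
    [
        ("LTR retrotransposons", None, 44.8, 49.6, 48.2, 47.0, 45.7, 45.9, 46.0),
        ("Ty1-copia", None, 22.9, 27.7, 26.2, 26.0, 24.8, 25.0, 24.8),
        ("SIRE/maximus", "LTR/Ty1-copia/SIRE-maximus", 17.0, 21.2, 19.7, 19.8, 18.8, 18.7, 18.4),
        ("Ty1-copia Other", "LTR/Ty1-copia/Other", 5.9, 6.6, 6.5, 6.2, 6.0, 6.3, 6.5),
        ("Ty3-gypsy", None, 17.5, 16.5, 16.8, 16.1, 16.0, 16.1, 16.2),
        ("Chromovirus", None, 8.1, 5.5, 6.6, 6.3, 6.4, 6.3, 6.4),
        ("CRM", "LTR/Ty3-gypsy/Chromovirus/CRM", 1.4, 0.7, 1.0, 1.0, 1.0, 0.9, 1.0),
        ("Tekay", "LTR/Ty3-gypsy/Chromovirus/Tekay", 6.3, 4.5, 5.2, 5.0, 5.1, 5.0, 5.0),
        ("Chromovirus Other", "LTR/Ty3-gypsy/Chromovirus/Other", 0.4, 0.3, 0.4, 0.4, 0.4, 0.4, 0.4),
        ("Non-chromovirus", None, 9.4, 11.0, 10.3, 9.8, 9.6, 9.8, 9.8),
        ("Athila", "LTR/Ty3-gypsy/Non-chromovirus/Athila", 3.2, 4.6, 4.0, 3.9, 3.8, 3.8, 3.7),
        ("Retand", "LTR/Ty3-gypsy/Non-chromovirus/Retand", 6.2, 6.4, 6.3, 5.9, 5.8, 6.0, 6.1),
        ("LTR unclassified", "LTR/Unclassified-LTR", 4.4, 5.4, 5.2, 5.0, 4.9, 4.9, 5.0),
        ("Non-LTR retrotransposons", None, 0.4, 0.4, 0.4, 0.4, 0.4, 0.4, 0.4),
        ("LINE", "Non-LTR/LINE", 0.4, 0.4, 0.4, 0.4, 0.4, 0.4, 0.4),
        ("DNA transposons", None, 0.4, 0.4, 0.4, 0.4, 0.4, 0.4, 0.4),
        ("hAT", "DNA/hAT", 0.3, 0.3, 0.3, 0.3, 0.2, 0.3, 0.3),
        ("MITE", "DNA/MITE", 0.06, 0.06, 0.06, 0.05, 0.05, 0.05, 0.06),
        ("DNA Other", "DNA/Other", 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1),
        ("Tandem repeats", None, 5.2, 1.9, 2.5, 4.6, 7.9, 5.8, 5.8),
        ("rDNA", "Tandem/rDNA", 0.4, 0.4, 0.3, 0.3, 0.2, 0.2, 0.3),
        ("satDNA", "Tandem/satDNA", 4.8, 1.5, 2.2, 4.3, 7.7, 5.6, 5.5),
        ("MITE-like", "Tandem/MITE-like", 3.6, 0.5, 1.0, 3.2, 6.6, 4.5, 4.5),
        ("Unclassified", "unclassified", 7.3, 8.6, 8.3, 8.0, 7.8, 7.9, 8.1),
        ("Total TEs", None, 45.6, 50.4, 48.9, 47.8, 46.5, 46.7, 46.9),
        ("Total repeats", None, 71.0, 73.8, 72.1, 73.3, 73.8, 73.0, 72.6),
    ],
    columns=["row", "lineage", *SPECIES],
).set_index("row")


def repeat_proportions() -> pd.DataFrame:
    """The proportion table as fractions (species columns only)."""
    return REPEAT_PROPORTIONS_PCT[list(SPECIES)] / 100.0


def genome_size_summaries(use_printed_2c: bool = True) -> dict[str, SpeciesSizeSummary]:
    """Species-size summaries from the published flow-cytometry table.

    ``use_printed_2c=False`` recomputes 2C Gbp from the 1C pg mean instead of
    taking the printed (rounded) 2C column; the two agree within 0.02 Gbp.
    """
    out = {}
    for sp, row in GENOME_SIZES.iterrows():
        size_2c = (
            float(row["size_2c_gbp"])
            if use_printed_2c
            else picograms_to_gigabases(float(row["mean_1c_pg"]), c_level=2)
        )
        out[sp] = SpeciesSizeSummary(
            species=str(sp),
            n=int(row["n"]),
            mean_1c_pg=float(row["mean_1c_pg"]),
            sem_1c_pg=float(row["sem_1c_pg"]),
            size_2c_gbp=size_2c,
        )
    return out
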