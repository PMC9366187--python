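"""Flow-cytometry genome-size summaries and the additive allopolyploid expectation.

Genome sizes enter the comparative repeat analysis in three places: they weight
the in-silico (additive) allopolyploid, they scale cluster proportions to
absolute genome amounts, and they set the per-species read allocation of a
comparative clustering run. This module summarizes per-plant 1C measurements
(picograms), converts pg to Gbp, builds the pairwise-combination additive
expectation with a t-based confidence interval, and tests pairwise species
differences with multiple-testing correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Standard flow-cytometry conversion: 1 pg of DNA corresponds to 0.978 Gbp.
PG_TO_GBP = 0.978


@dataclass(frozen=True)
class CytometrySample:
    """One plant's repeated flow-cytometry measurements.

    ``runs`` holds the per-run 1C values in picograms; the sample estimate is
    their arithmetic mean.
    """

    sample_id: str
    species: str
    ploidy: int
    runs: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4):
            raise ValueError(f"{self.sample_id}: ploidy must be 2 or 4, got {self.ploidy}")
        if len(self.runs) == 0:
            raise ValueError(f"{self.sample_id}: at least one run is required")
        if any(r <= 0 for r in self.runs):
            raise ValueError(f"{self.sample_id}: all 1C runs must be positive")
        object.__setattr__(self, "runs", tuple(float(r) for r in self.runs))

    @property
    def mean_1c_pg(self) -> float:
        return float(np.mean(self.runs))


@dataclass(frozen=True)
class SpeciesSizeSummary:
    """Per-species genome-size summary: mean 1C (pg), SEM, and 2C size in Gbp."""

    species: str
    n: int
    mean_1c_pg: float
    sem_1c_pg: float
    size_2c_gbp: float
    single_sample: bool = False


@dataclass(frozen=True)
class AdditiveSizeExpectation:
    """Additive (in silico) allopolyploid genome size from pairwise parent sums."""

    mean_1c_pg: float
    ci_low_1c_pg: float
    ci_high_1c_pg: float
    combinations: tuple[float, ...] = field(repr=False, default=())


def picograms_to_gigabases(value_pg: float, c_level: int = 1) -> float:
    """Convert a 1C amount in pg to Gbp at the requested C-level (1 or 2)."""
    if value_pg < 0:
        raise ValueError(f"DNA amount must be non-negative, got {value_pg} pg")
    if c_level not in (1, 2):
        raise ValueError(f"c_level must be 1 or 2, got {c_level}")
    return c_level * value_pg * PG_TO_GBP


def summarize_species(samples: list[CytometrySample], species: str) -> SpeciesSizeSummary:
    """Summarize all samples of one species: mean of per-sample means, SEM, 2C Gbp.

    SEM is the sample standard deviation (ddof=1) of per-sample means over
    sqrt(n); with a single sample it is reported as 0 and the summary flagged.
    """
    means = [s.mean_1c_pg for s in samples if s.species == species]
    if not means:
        known = sorted({s.species for s in samples})
        raise ValueError(f"no samples for species {species!r} (have {known})")
    n = len(means)
    mean = float(np.mean(means))
    if n == 1:
        warnings.warn(f"{species}: single sample, SEM reported as 0", stacklevel=2)
        sem = 0.0
    else:
        sem = float(np.std(means, ddof=1) / np.sqrt(n))
    return SpeciesSizeSummary(
        species=species,
        n=n,
        mean_1c_pg=mean,
        sem_1c_pg=sem,
        size_2c_gbp=picograms_to_gigabases(mean, c_level=2),
        single_sample=(n == 1),
    )


def additive_expectation(
    maternal: list[CytometrySample],
    paternal: list[CytometrySample],
    ci_level: float = 0.95,
) -> AdditiveSizeExpectation:
    """Additive genome-size expectation by pairwise combination of parent samples.

    Every maternal sample mean is summed with every paternal sample mean; the
    expectation is the mean of those sums and the CI is the t interval on them.
    With a single combination the CI degenerates to the point estimate.
    """
    if not maternal or not paternal:
        raise ValueError("both parental sides need at least one sample")
    if not 0 < ci_level < 1:
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level}")
    combos = tuple(
        m.mean_1c_pg + p.mean_1c_pg for m, p in itertools.product(maternal, paternal)
    )
    mean = float(np.mean(combos))
    n = len(combos)
    sd = float(np.std(combos, ddof=1)) if n > 1 else 0.0
    if n > 1 and sd > 0:
        half = stats.t.ppf(0.5 + ci_level / 2, df=n - 1) * sd / np.sqrt(n)
    else:
        half = 0.0
    return AdditiveSizeExpectation(
        mean_1c_pg=mean,
        ci_low_1c_pg=mean - half,
        ci_high_1c_pg=mean + half,
        combinations=combos,
    )


def pairwise_size_tests(
    samples: list[CytometrySample],
    equal_var: bool = False,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Two-sample t test per unordered species pair on per-sample 1C means.

    Welch's test by default (``equal_var=False``); p values are adjusted across
    all testable pairs (Benjamini-Hochberg by default). Pairs involving a
    species with fewer than two samples are reported as untestable with NaN
    statistics rather than silently dropped.
    """
    by_species: dict[str, list[float]] = {}
    for s in samples:
        by_species.setdefault(s.species, []).append(s.mean_1c_pg)
    species = sorted(by_species)
    rows = []
    for a, b in itertools.combinations(species, 2):
        xa, xb = by_species[a], by_species[b]
        testable = len(xa) >= 2 and len(xb) >= 2
        if testable:
            if np.var(xa) == 0 and np.var(xb) == 0:
                # degenerate zero-variance groups: no evidence of a difference
                # when the means coincide, certain difference otherwise
                t, p = (0.0, 1.0) if np.mean(xa) == np.mean(xb) else (np.inf, 0.0)
            else:
                t, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
            rows.append((a, b, True, float(t), float(p)))
        else:
            rows.append((a, b, False, np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["species_a", "species_b", "testable", "t_stat", "p_raw"]
    )
    table["p_adj"] = np.nan
    mask = table["testable"].to_numpy()
    if mask.any():
        _, adj, _, _ = multipletests(table.loc[mask, "p_raw"], method=method)
        table.loc[mask, "p_adj"] = adj
    return table


def relative_difference(a: float, b: float, baseline: str = "smaller") -> float:
    """|a - b| relative to the smaller (default) or larger of the two.

    The "smaller" baseline is the reading under which the two parental diploid
    genome sizes differ by more than 20% ((3.60-2.93)/2.93 = 22.9%).
    """
    if a < 0 or b < 0:
        raise ValueError("quantities must be non-negative")
    if a == 0 and b == 0:
        raise ValueError("relative difference undefined when both quantities are 0")
    if baseline == "smaller":
        denom = min(a, b)
        if denom == 0:
            raise ValueError("smaller baseline is 0; relative difference undefined")
    elif baseline == "larger":
        denom = max(a, b)
    else:
        raise ValueError(f"baseline must be 'smaller' or 'larger', got {baseline!r}")
    return abs(a - b) / denom


def read_measurements_csv(path) -> list[CytometrySample]:
    """Read long-format measurements (sample_id, species, ploidy, run_index, c1_pg)."""
    df = pd.read_csv(path)
    required = {"sample_id", "species", "ploidy", "c1_pg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurements file missing columns: {sorted(missing)}")
    samples = []
    for (sid, sp, pl), grp in df.groupby(["sample_id", "species", "ploidy"], sort=True):
        samples.append(
            CytometrySample(
                sample_id=str(sid), species=str(sp), ploidy=int(pl),
                runs=tuple(grp["c1_pg"]),
            )
        )
    return samples


def summaries_to_frame(summaries: list[SpeciesSizeSummary]) -> pd.DataFrame:
    """Species-size summaries as a table (species, n, mean 1C pg, SEM, 2C Gbp)."""
    return pd.DataFrame(
        {
            "species": [s.species for s in summaries],
            "n": [s.n for s in summaries],
            "mean_1c_pg": [s.mean_1c_pg for s in summaries],
            "sem_1c_pg": [s.sem_1c_pg for s in summaries],
            "size_2c_gbp": [s.size_2c_gbp for s in summaries],
        }
    )
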