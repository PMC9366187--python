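"""Ground-truth genome, read, and cluster-table simulation.

The generator emulates the study design end to end: two diploid parental
genomes with divergent repeat loads (the maternal genome smaller but enriched
for a MITE-like tandem repeat and chromoviral Ty3-gypsy; the paternal genome
larger and enriched for Ty1-copia and non-chromoviral Ty3-gypsy), and
allotetraploids built as the additive union of the parents with optional
per-family amplification placed on the subgenomes with a configurable bias.
Paired-end reads with a two-state quality profile, substitution errors, and an
organelle decoy feed the preprocessing/clustering stack; a fast path emits
comparative cluster tables directly with binomial sampling noise.

Every repeat family is grown from a single consensus monomer shared by both
parents, with small per-copy divergence, so that reads from homologous copies
in different species share exact k-mers and co-cluster. All randomness flows
from one integer seed; outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._kmers import reverse_complement
from .annotate import DomainHitTable, validate_lineage
from .genomesize import CytometrySample
from .preprocess import ReadPair

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
SINGLE_COPY = "single-copy"
ORGANELLE = "organelle"


@dataclass(frozen=True)
class RepeatFamilySpec:
    """Simulator-side ground truth for one repeat family."""

    name: str
    lineage: str
    monomer: str
    arrangement: str  # "dispersed" | "tandem"
    copies: int
    divergence: float = 0.002
    amplification: float = 1.0
    subgenome_bias: float = 0.5

    def __post_init__(self) -> None:
        validate_lineage(self.lineage)
        if self.arrangement not in ("dispersed", "tandem"):
            raise ValueError(f"{self.name}: arrangement must be dispersed or tandem")
        if not 60 <= len(self.monomer) <= 5000:
            raise ValueError(f"{self.name}: monomer must be 60-5000 bp")
        if self.copies < 0:
            raise ValueError(f"{self.name}: copies must be >= 0")
        if not 0 <= self.divergence <= 0.3:
            raise ValueError(f"{self.name}: divergence must be in [0, 0.3]")
        if self.amplification < 0:
            raise ValueError(f"{self.name}: amplification must be >= 0")
        if not 0 <= self.subgenome_bias <= 1:
            raise ValueError(f"{self.name}: subgenome_bias must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """One seed plus the read-level and genome-level generator knobs."""

    seed: int
    read_length: int = 150
    pairs_per_genome: int = 20_000
    error_rate: float = 0.002
    quality_high: int = 38
    quality_low: int = 10
    low_quality_tail_frac: float = 0.02
    insert_size: int = 300
    genome_backbone_length: int = 1_000_000
    organelle_fraction: float = 0.0
    organelle_length: int = 150_000

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.insert_size < self.read_length:
            raise ValueError("insert_size must be >= read_length")


@dataclass
class Genome:
    """A simulated genome: sequence plus a truth table of repeat intervals.

    ``intervals`` holds (start, end, family, subgenome) for every repeat copy
    or tandem array; positions not covered are single-copy backbone.
    ``family_copies`` counts monomer copies per family per subgenome.
    """

    name: str
    sequence: str
    intervals: list[tuple[int, int, str, str]] = field(default_factory=list)
    family_copies: dict[str, dict[str, int]] = field(default_factory=dict)
    specs: dict[str, RepeatFamilySpec] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def family_fractions(self) -> dict[str, float]:
        """Realized base-pair fraction per family (from the truth intervals)."""
        bases: dict[str, int] = {}
        for s, e, fam, _sub in self.intervals:
            bases[fam] = bases.get(fam, 0) + (e - s)
        return {fam: b / self.length for fam, b in bases.items()}


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute bases at the given per-base rate (always to a different base)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size:
        # map current base to one of the other three
        idx = np.searchsorted(_BASES, arr[hits])
        arr[hits] = _BASES[(idx + rng.integers(1, 4, size=hits.size)) % 4]
    return arr.tobytes().decode("ascii")


def _family_pieces(
    spec: RepeatFamilySpec,
    copies: int,
    rng: np.random.Generator,
    max_array: int = 30,
) -> list[tuple[str, str]]:
    """Genomic pieces for ``copies`` copies of a family: (family, sequence).

    Dispersed copies become one piece each; tandem copies are grouped into
    head-to-tail arrays of up to ``max_array`` monomers.
    """
    pieces = []
    if spec.arrangement == "dispersed":
        for _ in range(copies):
            pieces.append((spec.name, _mutate(spec.monomer, spec.divergence, rng)))
    else:
        left = copies
        while left > 0:
            k = min(max_array, left)
            arr = "".join(_mutate(spec.monomer, spec.divergence, rng) for _ in range(k))
            pieces.append((spec.name, arr))
            left -= k
    return pieces


def _assemble(
    name: str,
    backbone: str,
    pieces: list[tuple[str, str]],
    subgenome: str,
    rng: np.random.Generator,
) -> Genome:
    """Interleave repeat pieces with backbone chunks at random cut points."""
    cuts = np.sort(rng.integers(0, len(backbone) + 1, size=len(pieces)))
    parts: list[str] = []
    intervals: list[tuple[int, int, str, str]] = []
    pos = 0
    prev = 0
    order = rng.permutation(len(pieces))
    for cut, pi in zip(cuts, order):
        chunk = backbone[prev:cut]
        parts.append(chunk)
        pos += len(chunk)
        fam, seq = pieces[pi]
        parts.append(seq)
        intervals.append((pos, pos + len(seq), fam, subgenome))
        pos += len(seq)
        prev = cut
    parts.append(backbone[prev:])
    return Genome(name=name, sequence="".join(parts), intervals=intervals)


def _build_parent(
    name: str,
    specs: Sequence[RepeatFamilySpec],
    backbone_length: int,
    rng: np.random.Generator,
) -> Genome:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate family names in specs for {name}")
    repeat_bases = sum(s.copies * len(s.monomer) for s in specs)
    total = backbone_length + repeat_bases
    if repeat_bases > 0.95 * total:
        raise ValueError(
            f"{name}: total repeat content {repeat_bases / total:.1%} exceeds 95% "
            "of the genome; backbone cannot be resolved"
        )
    backbone = _random_sequence(rng, backbone_length)
    pieces = []
    for s in specs:
        pieces.extend(_family_pieces(s, s.copies, rng))
    genome = _assemble(name, backbone, pieces, subgenome=name, rng=rng)
    genome.family_copies = {s.name: {name: s.copies} for s in specs}
    genome.specs = {s.name: s for s in specs}
    return genome


def simulate_parents(
    maternal_specs: Sequence[RepeatFamilySpec],
    paternal_specs: Sequence[RepeatFamilySpec],
    config: SimulationConfig,
    maternal_backbone: int | None = None,
    paternal_backbone: int | None = None,
    maternal_name: str = "maternal",
    paternal_name: str = "paternal",
) -> tuple[Genome, Genome]:
    """Build the two labelled parental genomes (truth in Genome.intervals)."""
    rng = np.random.default_rng(config.seed)
    m = _build_parent(
        maternal_name, maternal_specs,
        maternal_backbone or config.genome_backbone_length, rng,
    )
    p = _build_parent(
        paternal_name, paternal_specs,
        paternal_backbone or config.genome_backbone_length, rng,
    )
    return m, p


def _insert_pieces(
    genome: Genome,
    pieces: list[tuple[str, str]],
    subgenome: str,
    region: tuple[int, int],
    rng: np.random.Generator,
) -> Genome:
    """Insert pieces at random backbone positions inside ``region``.

    Cut points avoid existing repeat intervals so earlier copies stay intact.
    """
    if not pieces:
        return genome
    lo, hi = region
    blocked = sorted((s, e) for s, e, _f, _s in genome.intervals if s < hi and e > lo)
    gaps = []
    cursor = lo
    for s, e in blocked:
        if s > cursor:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < hi:
        gaps.append((cursor, hi))
    gap_lens = np.array([e - s for s, e in gaps], dtype=np.int64)
    total_gap = int(gap_lens.sum())
    if total_gap <= 0:
        raise ValueError(f"{genome.name}: no backbone left in {region} for insertion")
    offsets = np.sort(rng.integers(0, total_gap, size=len(pieces)))
    bounds = np.cumsum(gap_lens)
    positions = []
    for off in offsets:
        gi = int(np.searchsorted(bounds, off, side="right"))
        positions.append(gaps[gi][0] + int(off - (bounds[gi - 1] if gi else 0)))
    order = rng.permutation(len(pieces))
    seq = genome.sequence
    parts = []
    new_intervals = []
    shift_at: list[tuple[int, int]] = []  # (original position, inserted length)
    prev = 0
    shift = 0
    for pos, pi in zip(positions, order):
        fam, piece = pieces[pi]
        parts.append(seq[prev:pos])
        new_intervals.append((pos + shift, pos + shift + len(piece), fam, subgenome))
        parts.append(piece)
        shift += len(piece)
        shift_at.append((pos, shift))
        prev = pos
    parts.append(seq[prev:])
    old_positions = np.array([p for p, _ in shift_at])
    shifts = np.array([s for _, s in shift_at])

    def shifted(x: int) -> int:
        i = int(np.searchsorted(old_positions, x, side="right"))
        return x + (int(shifts[i - 1]) if i else 0)

    intervals = [
        (shifted(s), shifted(s) + (e - s), fam, sub)
        for s, e, fam, sub in genome.intervals
    ]
    intervals.extend(new_intervals)
    intervals.sort()
    return Genome(
        name=genome.name,
        sequence="".join(parts),
        intervals=intervals,
        family_copies=genome.family_copies,
        specs=genome.specs,
    )


def simulate_allopolyploid(
    maternal: Genome,
    paternal: Genome,
    amplification_map: Mapping[str, float],
    config: SimulationConfig,
    name: str = "allopolyploid",
) -> Genome:
    """Additive union of the parents plus per-family amplification.

    Extra copies bring each named family to ``amplification x additive copies``,
    split between subgenomes by the family's ``subgenome_bias`` (fraction on
    the maternal subgenome). ``amplification = 1`` is strict additivity.
    """
    known = set(maternal.specs) | set(paternal.specs)
    unknown = set(amplification_map) - known
    if unknown:
        raise ValueError(f"amplification map names unknown families: {sorted(unknown)}")
    offset = maternal.length
    intervals = list(maternal.intervals) + [
        (s + offset, e + offset, fam, sub) for s, e, fam, sub in paternal.intervals
    ]
    copies: dict[str, dict[str, int]] = {}
    for fam in known:
        copies[fam] = {}
        for g in (maternal, paternal):
            for sub, c in g.family_copies.get(fam, {}).items():
                copies[fam][sub] = copies[fam].get(sub, 0) + c
    genome = Genome(
        name=name,
        sequence=maternal.sequence + paternal.sequence,
        intervals=intervals,
        family_copies=copies,
        specs={**paternal.specs, **maternal.specs},
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7, len(name)]))
    m_end = offset  # current end of the maternal subgenome span
    for fam in sorted(amplification_map):
        amp = amplification_map[fam]
        spec = genome.specs[fam]
        additive = sum(copies.get(fam, {}).values())
        extra = int(round((amp - 1) * additive))
        if extra <= 0:
            continue
        extra_m = int(round(spec.subgenome_bias * extra))
        extra_p = extra - extra_m
        before = genome.length
        genome = _insert_pieces(
            genome, _family_pieces(spec, extra_m, rng), maternal.name,
            (0, m_end), rng,
        )
        m_end += genome.length - before
        genome = _insert_pieces(
            genome, _family_pieces(spec, extra_p, rng), paternal.name,
            (m_end, genome.length), rng,
        )
        genome.family_copies.setdefault(fam, {})
        genome.family_copies[fam][maternal.name] = (
            genome.family_copies[fam].get(maternal.name, 0) + extra_m
        )
        genome.family_copies[fam][paternal.name] = (
            genome.family_copies[fam].get(paternal.name, 0) + extra_p
        )
    return genome


def _interval_label(
    starts: np.ndarray, ends: np.ndarray, fams: list[str],
    s: int, e: int,
) -> tuple[str, bool]:
    """Majority family of [s, e) against sorted intervals; ('single-copy', False)
    when most bases are backbone. The flag marks full containment in one copy."""
    i = int(np.searchsorted(ends, s, side="right"))
    best_fam, best_ov = SINGLE_COPY, 0
    covered = 0
    while i < starts.size and starts[i] < e:
        ov = min(e, int(ends[i])) - max(s, int(starts[i]))
        if ov > 0:
            covered += ov
            if ov > best_ov:
                best_fam, best_ov = fams[i], ov
            if int(starts[i]) <= s and int(ends[i]) >= e:
                return fams[i], True
        i += 1
    if best_ov * 2 < (e - s):
        return SINGLE_COPY, False
    return best_fam, False


def simulate_reads(
    genome: Genome,
    config: SimulationConfig,
    n_pairs: int | None = None,
    organelle_seq: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Paired reads with qualities, errors, optional organelle decoy, and truth.

    Fragments start uniformly; mate 2 is the reverse complement of the fragment
    end. The truth table records, per mate, the majority-origin family of its
    genomic interval and whether it lies fully within a single repeat copy.
    """
    n = n_pairs if n_pairs is not None else config.pairs_per_genome
    rl, ins = config.read_length, config.insert_size
    if genome.length < ins:
        raise ValueError(f"{genome.name}: genome shorter than one fragment")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11, genome.length]))
    from_organelle = (
        rng.random(n) < config.organelle_fraction
        if (config.organelle_fraction > 0 and organelle_seq is not None)
        else np.zeros(n, dtype=bool)
    )
    starts_g = rng.integers(0, genome.length - ins + 1, size=n)
    if from_organelle.any():
        starts_o = rng.integers(0, len(organelle_seq) - ins + 1, size=n)
    ivals = sorted(genome.intervals)
    iv_starts = np.array([s for s, *_ in ivals], dtype=np.int64)
    iv_ends = np.array([e for _s, e, *_ in ivals], dtype=np.int64)
    iv_fams = [f for _s, _e, f, _sub in ivals]
    pairs: list[ReadPair] = []
    truth_rows = []
    for i in range(n):
        if from_organelle[i]:
            src, s = organelle_seq, int(starts_o[i])
        else:
            src, s = genome.sequence, int(starts_g[i])
        frag = src[s : s + ins]
        seq1 = _mutate(frag[:rl], config.error_rate, rng)
        seq2 = _mutate(reverse_complement(frag)[:rl], config.error_rate, rng)
        q1 = _quality_string(rl, config, rng)
        q2 = _quality_string(rl, config, rng)
        rid = f"{genome.name}.{i}"
        pairs.append(ReadPair(id=rid, seq1=seq1, seq2=seq2, qual1=q1, qual2=q2))
        if from_organelle[i]:
            fam1 = fam2 = ORGANELLE
            full1 = full2 = True
        else:
            fam1, full1 = _interval_label(iv_starts, iv_ends, iv_fams, s, s + rl)
            fam2, full2 = _interval_label(iv_starts, iv_ends, iv_fams, s + ins - rl, s + ins)
        truth_rows.append((rid, s, fam1, full1, fam2, full2))
    truth = pd.DataFrame(
        truth_rows,
        columns=["pair_id", "start", "family_1", "within_copy_1", "family_2", "within_copy_2"],
    )
    return pairs, truth


def _quality_string(n: int, config: SimulationConfig, rng: np.random.Generator) -> str:
    low = rng.random(n) < config.low_quality_tail_frac
    q = np.where(low, config.quality_low, config.quality_high).astype(np.uint8) + 33
    return q.tobytes().decode("ascii")


def random_organelle(config: SimulationConfig) -> str:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    return _random_sequence(rng, config.organelle_length)


def truth_hit_table(
    truth: pd.DataFrame,
    lineages: Mapping[str, str],
    source: str,
    hit_rate: float,
    seed: int,
) -> DomainHitTable:
    """Ground-truth domain hits standing in for a protein-domain database.

    Each mate that lies fully within a repeat copy receives its family's
    lineage with probability ``hit_rate`` (domains cover only part of an
    element, so not every read hits one).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    table = DomainHitTable(source=source)
    for _, row in truth.iterrows():
        for mate in (1, 2):
            fam = row[f"family_{mate}"]
            if fam in (SINGLE_COPY, ORGANELLE) or not row[f"within_copy_{mate}"]:
                continue
            if fam in lineages and rng.random() < hit_rate:
                table.add(f"{row['pair_id']}/{mate}", lineages[fam])
    return table


def simulate_cytometry(
    species: str,
    ploidy: int,
    mean_1c_pg: float,
    sem_1c_pg: float,
    n_samples: int,
    rng: np.random.Generator,
    runs_per_sample: int = 3,
    run_cv: float = 0.005,
) -> list[CytometrySample]:
    """Per-plant 1C measurements consistent with a species mean and SEM.

    Sample means are normal with SD = SEM * sqrt(n); within-sample runs scatter
    with a small coefficient of variation around the sample mean.
    """
    sd = sem_1c_pg * np.sqrt(n_samples)
    samples = []
    for i in range(n_samples):
        m = rng.normal(mean_1c_pg, sd)
        runs = rng.normal(m, run_cv * m, size=runs_per_sample)
        samples.append(
            CytometrySample(
                sample_id=f"{species}_{i + 1}", species=species, ploidy=ploidy,
                runs=tuple(np.abs(runs)),
            )
        )
    return samples


def simulate_cluster_table(
    specs_per_species: Mapping[str, Sequence[RepeatFamilySpec]],
    genome_sizes_1c: Mapping[str, float],
    maternal: str,
    paternal: str,
    depth: int,
    seed: int,
    backbone_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Fast path: a comparative table from spec fractions + binomial noise.

    Per species, family read counts are multinomial at ``depth`` effective
    reads over the family base-pair fractions; ``true_<species>`` columns carry
    the noise-free fractions for testing. Rows are families; the in_silico
    column uses the supplied parental genome sizes.
    """
    from .comparative import in_silico_expectation

    species = sorted(specs_per_species)
    if maternal not in species or paternal not in species:
        raise ValueError("maternal and paternal must be among the species")
    fam_names: list[str] = []
    lineages: dict[str, str] = {}
    for sp in species:
        for spec in specs_per_species[sp]:
            if spec.name not in fam_names:
                fam_names.append(spec.name)
                lineages[spec.name] = spec.lineage
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    truth: dict[str, np.ndarray] = {}
    for sp in species:
        specs = {s.name: s for s in specs_per_species[sp]}
        repeat_bases = {
            name: (specs[name].copies * len(specs[name].monomer) if name in specs else 0)
            for name in fam_names
        }
        if backbone_lengths is not None:
            total = backbone_lengths[sp] + sum(repeat_bases.values())
        else:
            total = genome_sizes_1c[sp]
        fracs = np.array([repeat_bases[n] / total for n in fam_names])
        if fracs.sum() > 1:
            raise ValueError(f"{sp}: family fractions sum to more than 1")
        probs = np.append(fracs, 1 - fracs.sum())
        counts = rng.multinomial(depth, probs)[:-1]
        data[sp] = counts / depth
        truth[sp] = fracs
    rows = pd.DataFrame(data, index=fam_names)
    rows.insert(0, "lineage", [lineages[n] for n in fam_names])
    for sp in species:
        rows[f"true_{sp}"] = truth[sp]
    rows["in_silico"] = [
        in_silico_expectation(
            rows.loc[n, maternal], rows.loc[n, paternal],
            genome_sizes_1c[maternal], genome_sizes_1c[paternal],
        )
        for n in fam_names
    ]
    rows.index.name = "cluster_id"
    polyploids = [sp for sp in species if sp not in (maternal, paternal)]
    rows.attrs.update(maternal=maternal, paternal=paternal, polyploids=polyploids)
    return rows


# ---------------------------------------------------------------------------
# The study-system-like preset

#: Per-family targets: lineage, monomer length, arrangement, and base-pair
#: fractions in the maternal and paternal genome. Fractions follow the
#: published per-species repeat-proportion estimates, collapsed to one family
#: per major lineage (the unclassified fraction is left as backbone).
PRESET_FAMILIES: dict[str, tuple[str, int, str, float, float]] = {
    "SIRE": ("LTR/Ty1-copia/SIRE-maximus", 5000, "dispersed", 0.170, 0.212),
    "Ty1_other": ("LTR/Ty1-copia/Other", 5000, "dispersed", 0.059, 0.066),
    "Chromovirus": ("LTR/Ty3-gypsy/Chromovirus/Tekay", 5000, "dispersed", 0.081, 0.055),
    "Non_chromovirus": ("LTR/Ty3-gypsy/Non-chromovirus/Athila", 5000, "dispersed", 0.094, 0.110),
    "LTR_unclassified": ("LTR/Unclassified-LTR", 5000, "dispersed", 0.044, 0.054),
    "satDNA": ("Tandem/satDNA", 170, "tandem", 0.048, 0.015),
    "rDNA": ("Tandem/rDNA", 500, "tandem", 0.004, 0.004),
    "MITE_like": ("Tandem/MITE-like", 300, "tandem", 0.036, 0.005),
}

#: LTR families, for the mild-amplification polyploid preset.
PRESET_LTR_FAMILIES = (
    "SIRE", "Ty1_other", "Chromovirus", "Non_chromovirus", "LTR_unclassified",
)

#: Simulated parental genome lengths (bp); ratio matches the parents' 1C sizes
#: (2.93 : 3.60 pg). Absolute scale is set so that genome-skimming depths of a
#: few times 1e4 read pairs leave single-copy coverage well below the level at
#: which overlapping backbone reads would chain into spurious clusters.
PRESET_MATERNAL_LENGTH = 7_000_000
PRESET_PATERNAL_LENGTH = int(round(PRESET_MATERNAL_LENGTH * 3.60 / 2.93))

#: Polyploid amplification presets: "young" is strictly additive; in
#: "intermediate" the MITE-like tandem repeat has amplified 4x and LTR
#: families mildly (1.1x); "triple_mite" isolates a 3x MITE-like amplification.
PRESET_AMPLIFICATIONS: dict[str, dict[str, float]] = {
    "young": {},
    "intermediate": {"MITE_like": 4.0, **{f: 1.1 for f in PRESET_LTR_FAMILIES}},
    "triple_mite": {"MITE_like": 3.0},
}


def preset_parent_specs(
    seed: int,
    divergence: float = 0.002,
    mite_bias: float = 0.6,
) -> tuple[list[RepeatFamilySpec], list[RepeatFamilySpec], int, int]:
    """Family specs and backbone lengths for the two preset parents.

    Returns (maternal_specs, paternal_specs, maternal_backbone,
    paternal_backbone). Monomers are drawn once per family and shared between
    parents so homologous copies co-cluster.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    maternal, paternal = [], []
    m_repeat = p_repeat = 0
    for name in PRESET_FAMILIES:
        lineage, mlen, arrangement, f_m, f_p = PRESET_FAMILIES[name]
        monomer = _random_sequence(rng, mlen)
        bias = mite_bias if name == "MITE_like" else 0.5
        c_m = int(round(f_m * PRESET_MATERNAL_LENGTH / mlen))
        c_p = int(round(f_p * PRESET_PATERNAL_LENGTH / mlen))
        common = dict(
            lineage=lineage, monomer=monomer, arrangement=arrangement,
            divergence=divergence, subgenome_bias=bias,
        )
        maternal.append(RepeatFamilySpec(name=name, copies=c_m, **common))
        paternal.append(RepeatFamilySpec(name=name, copies=c_p, **common))
        m_repeat += c_m * mlen
        p_repeat += c_p * mlen
    return (
        maternal,
        paternal,
        PRESET_MATERNAL_LENGTH - m_repeat,
        PRESET_PATERNAL_LENGTH - p_repeat,
    )


def preset_lineages() -> dict[str, str]:
    return {name: vals[0] for name, vals in PRESET_FAMILIES.items()}
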