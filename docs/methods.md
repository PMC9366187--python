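# Methods

## The model

The analysis treats a repeat family's genome proportion as directly estimable
from unassembled low-coverage reads: reads are clustered by sequence
similarity, and a cluster's share of all analysed reads of a species estimates
the fraction of that species' genome occupied by the family. For an
allopolyploid formed from a maternal parent (1C size `g_m`, cluster proportion
`p_m`) and a paternal parent (`g_p`, `p_p`), the additive null — what the
polyploid should contain if genome merger changed nothing — is the
genome-size-weighted mixture

    E = (p_m·g_m + p_p·g_p) / (g_m + g_p),

because a comparative clustering run allocates reads to species proportionally
to genome size, so the parental read pools combine with exactly these weights.
Departures are expressed as a normalized deviation

    D = (obs − E) / max(obs, E),

bounded in [−1, 1], zero at additivity, −1 at total loss, and antisymmetric in
its arguments. This realization was chosen over a log₂ ratio (provided as an
alternative) because it stays finite at zero proportions and maps loss and
gain onto a symmetric bounded scale; the defining constraints are only the
range, the zero point, and monotonicity.

Classification thresholds follow the source analysis: clusters below
proportion 0.001 in every species are dropped (keeping clusters large in only
one species, which is what the comparison is about; an "any species" mode
exists); parental origin requires a relative difference ≥ 20% of the larger
parental proportion (boundary inclusive), otherwise "similar"; a cluster is
retained as deviating when at least one polyploid differs from `E` by strictly
more than 20% of `E`. Origin uses ≥ (a stated minimum), retention uses >
(a stated exceedance); the deviation denominator is the expected value, the
origin denominator the larger parent.

Absolute amounts are `proportion × genome size` with the basis stated
explicitly per row: parental totals are reported on the monoploid (1C) basis,
per-family amounts and polyploid net amounts on the holoploid (2C) basis,
matching how the derived quantities couple the two published tables. Flow
cytometry picograms convert at 1 pg = 0.978 Gbp, the standard conversion; it
reproduces every printed 2C cell from its 1C mean within 0.02 Gbp (printed
rounding).

The additive genome-size expectation is built sample-wise: every maternal
sample mean is summed with every paternal sample mean, the expectation is the
mean of those pairwise sums, and the confidence interval is the t interval on
them (`ci_level` exposed; 95% default). Species differences use Welch's
two-sample t test on per-sample means (equal-variance Student optional) with
Benjamini–Hochberg adjustment (method parameter exposed). Zero-variance
degenerate groups are assigned p = 1 when means coincide (no evidence of
difference) rather than propagating a 0/0 statistic.

## Read preparation

A pair is kept when the count of bases below Q20 across *both* mates is at
most 5% of their combined length (boundary inclusive) and neither mate
contains an N (the N rule is folded into quality filtering here, since adapter
trimming is out of scope for simulated reads; a pass-through hook exists).
Survivors are truncated to their first 125 bp; a pair with a shorter mate is
discarded, so every analysed read carries equal weight. Organelle
(plastid-like) pairs are removed without alignment: a pair is dropped when
either mate shares ≥ 80% of its canonical 31-mers with the organelle
reference. This k-mer criterion is a stand-in for alignment-based filtering,
not equivalent to it: it removes exact organelle reads completely with no
false removals, but a single sequencing error can shield a read (an error
kills up to k of its k-mers), so a small fraction of erroneous organelle reads
leaks through. Quality fractions are evaluated on the reads as given, so the
preparation is idempotent once reads are at the trim length.

## Clustering

Reads (mates enter independently, carrying their pair id) are nodes of a
graph with an edge when two reads share ≥ 55% of the smaller read's canonical
17-mers; repeat clusters are connected components with at least
`0.00005 × analysed reads` members, ranked by size (ties broken by smallest
member id, so ranking is invariant under relabeling). This is a deliberately
simplified desk-scale stand-in for graph-layout repeat clustering — connected
components suffice when simulated families are well separated — and is **not**
a reimplementation of the published clustering tool. Two code paths share the
contract: an explicit graph (exact, small inputs) and a union-find that
evaluates, per read, candidate neighbours drawn from an inverted k-mer index
with a per-k-mer cap (24) on candidates, skipping candidates already in the
same component. Similarity is always computed exactly on full k-mer profiles;
the cap only sparsifies which edges are *tested*, which leaves connected
components unchanged when families are internally dense (every read of a
family shares k-mers with many others) — the regime the generator produces.
K-mers occurring in a single read are never indexed; they cannot form an edge.

## The synthetic-data generator

The generator emulates the study design: a maternal-like diploid (7.0 Mb) and
a paternal-like diploid (8.6 Mb; sizes in the published 2.93 : 3.60 ratio)
carrying eight repeat families whose base-pair fractions follow the published
per-species proportion table collapsed to one family per major lineage —
Ty1-copia (SIRE 17.0/21.2%, other 5.9/6.6%), chromoviral and non-chromoviral
Ty3-gypsy (8.1/5.5% and 9.4/11.0%), unclassified LTR (4.4/5.4%), satDNA
(4.8/1.5%), rDNA (0.4/0.4%), and the MITE-like tandem repeat (3.6/0.5%,
enriched in the *smaller* maternal genome). Dispersed families use 5 kb
monomers, tandem families 170–500 bp monomers emitted as head-to-tail arrays
of up to 30 copies. Allopolyploids are the additive union of the parents plus
per-family amplification: preset "young" is strictly additive, "intermediate"
amplifies the MITE-like family 4× (60% of new copies on the maternal
subgenome) and LTR families mildly (1.1×), and "triple_mite" isolates a 3×
MITE-like amplification as a clean anchor for deviation recovery.

Reads are 150 bp pairs from 300 bp fragments at uniform positions (fragment-
length realism is irrelevant to proportions), with substitution errors at
0.002/bp and a two-state quality profile (Q38 with a 2% tail at Q10 —
sufficient to exercise the 5% low-quality boundary, not a learned profile).
A configurable fraction of pairs (2% in the pipeline) comes from a simulated
organelle decoy. The truth table records every repeat interval and every
read's origin.

Two generator constants are load-bearing and chosen by design analysis, not
fitting. First, within-family copy divergence (0.002/copy) and the error rate
together bound the number of mismatch events per 125 bp read: each event
destroys up to 17 of a read's 109 17-mers, and a read with ≥ 3 events cannot
reach the 0.55 similarity threshold against any partner, so rates must keep
P(≥ 3 events) small (~1.4% at 0.002 + 0.002). Real repeat families are far
more diverged; real pipelines tolerate this by aligning with mismatches
rather than requiring exact k-mer identity. Passing tests therefore show the
*quantification pipeline* is correct, not that exact-k-mer clustering would
resolve old, diverged families in real data. Second, parental genome lengths
are set so that at ~10⁵ analysed read pairs the single-copy backbone sees
< 0.005 read starts per bp; overlapping backbone reads then almost never
chain into components above the minimum cluster size (backbone contamination
of repeat totals < 0.1%). Both parents draw each family's copies from one
shared consensus monomer, so homologous clusters merge across species — real
parents would carry species-specific variants; the generator does not model
that, nor insertion mechanics (TSDs, nesting), recombination, or indels.

Annotation ground truth stands in for a protein-domain database: each mate
fully inside a repeat copy carries its family's lineage with probability 0.3
(domains cover only part of an element). Comparative clusters then inherit
annotations through the transfer rule: majority label transferred iff ≥ 20% of
member reads are annotated, the unannotated share exceeds 50%, and no second
label also reaches 20% (a majority conflict is never overridden; ties break
lexicographically and are flagged).

## Statistical reporting of recovery

Recovery of simulated fractions is judged against binomial sampling error with
the **read pair** as the unit: both mates of a 300 bp fragment almost always
originate from the same repeat interval, so mates are not independent draws
and a mate-based SE would understate the variance. At the default depth
(8×10⁴ comparative pairs allocated across 5 genomes proportionally to size,
~1.05×10⁵ pairs simulated) every family in every genome is recovered within
3 SE, with a residual capture bias well inside that band (boundary reads
overlapping a family by fewer than ~76 bp cannot pass the similarity
threshold, costing ~0.5–2% of a family's reads depending on monomer length).

Exactness claims (origin classes, retention flags) are asserted wherever they
are statistically decidable at the realized counts: a class is checked when
the true quantity sits more than 3 sampling SD from its 20% decision boundary.
This matters for the rarest family (rDNA at 0.4%: ~75 pairs per genome, SD of
its measured deviation ~14%, boundary only 1.4 SD away) and for additive
tandem repeats in the 4×-MITE polyploid, whose true deviation is −9.5% — not
zero — because the amplified MITE dilutes every other family's proportion.
That dilution is a real property of proportion-based repeat analysis, visible
in the source data as the slight decrease of other repeat classes where the
MITE-like element amplified. For the same reason a family amplified a-fold
has expected deviation slightly below (a−1)/a: the measured anchor for the 3×
family is 1 − G'/(3·G_additive), ≈ 0.65 at preset composition.

The ±20% deviation is measured on proportions relative to the in-silico
expectation (the natural reading of "difference to the expected value"); an
alternative mode on genome-size-scaled amounts is provided, and the two
differ exactly when the polyploid genome size departs from additivity.

## Defaults and degenerate inputs

| parameter | default | meaning |
|---|---|---|
| q_min / max_frac | Q20 / 5% | low-quality filter, boundary inclusive |
| trim length | 125 bp | common read length after truncation |
| organelle k / hit_frac | 31 / 0.8 | canonical k-mer membership filter |
| clustering k / min_similarity | 17 / 0.55 | shared fraction of smaller profile |
| min cluster size | 5×10⁻⁵ × reads | components below count as singletons |
| min_proportion | 0.001 | cluster size filter, "all species" mode |
| origin / deviation threshold | 0.20 / 0.20 | ≥ for origin, > for retention |
| pg→Gbp | 0.978 | flow-cytometry conversion |
| ci_level | 0.95 | t interval on pairwise combination sums |

Degenerate cases are defined rather than crashed where a convention is
defensible (deviation 0/0 → 0; single cytometry sample → SEM 0 with a warning
flag; reads shorter than k pass the organelle filter with a warning) and
rejected where the input is meaningless (both parents zero for origin
classification; zero analysed totals; k ≥ read length; negative DNA amounts).

## Known limitations

* Exact-k-mer similarity cannot resolve diverged repeat families; the
  generator's low divergence is what makes components equal families.
* Connected components merge families that share any dense sequence bridge;
  no graph-layout community detection is attempted.
* The published cluster-level proportions themselves are not reproducible at
  desk scale from raw data (that requires the deposited reads and the
  published clustering tool); they enter as fixed inputs, and clustering
  correctness is established on synthetic data instead.
* Subgenome assignment of reads is not attempted (the source establishes
  subgenome placement cytogenetically); the simulator tracks it only as
  ground truth.
* The "13.5% enlargement" of older polyploids depends on the baseline; from
  the printed tables the combination-mean baseline gives ~12%, so the driver
  reports the value with its baseline rather than hard-coding a number.
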