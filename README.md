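# repeatscape

Comparative repeat-landscape analysis for allopolyploids and their diploid
parents from low-coverage ("genome skimming") paired-end reads.

## The problem

When two diploid species hybridize and double their genomes, the resulting
allopolyploid inherits one repeat complement from each parent. Whether its
transposable elements and tandem repeats then stay **additive** — each family
present at exactly the summed parental copy number — or amplify ("genomic
shock") is a central question of polyploid genome evolution. Because repeats
dominate large plant genomes, the question can be answered without an
assembly: cluster low-coverage reads by sequence similarity, and each
cluster's share of the analysed reads estimates the genome proportion of one
repeat family.

`repeatscape` implements that analysis end to end for the marsh-orchid model
system (maternal diploid *Dactylorhiza fuchsii*, paternal *D. incarnata*, and
their sibling allotetraploids), and ships a ground-truth simulator so every
step is testable without any sequencing data.

## The core quantities

For a repeat cluster with proportions `p_m` and `p_p` in the maternal and
paternal parent (1C genome sizes `g_m`, `g_p`):

* **in-silico allopolyploid expectation** (the additive null; a comparative
  run samples reads proportionally to genome size, so parental read pools mix
  with these weights):

  `E = (p_m·g_m + p_p·g_p) / (g_m + g_p)`

* **normalized deviation** of an observed polyploid proportion `o` from the
  expectation `e`, in [−1, 1], 0 at additivity, antisymmetric:

  `D = (o − e) / max(o, e)`

* **parental origin**: maternal-larger / paternal-larger when
  `|p_m − p_p| / max(p_m, p_p) ≥ 0.20`, otherwise "similar";
  a cluster is **retained** as deviating when at least one polyploid has
  `|o − e| / e > 0.20` (clusters below proportion 0.001 in every species are
  dropped first).

* **absolute amounts**: `proportion × genome size` at an explicit basis
  (monoploid 1C or holoploid 2C), converting flow-cytometry picograms at
  1 pg = 0.978 Gbp.

Modules: `genomesize` (cytometry summaries, additive expectation + CI, Welch
t tests with Benjamini–Hochberg), `preprocess` (paired-read quality filter,
125 bp trimming, k-mer organelle removal), `clustering` (similarity graph /
union-find components, genome-proportional sampling, cluster proportions),
`annotate` (majority domain-hit annotation, cross-run transfer, taxonomy
aggregation), `comparative` (everything above), `simdata` (ground-truth
genomes, reads, cluster tables), `pipeline` (end-to-end orchestration).

## Worked example

```python
>>> from repeatscape.comparative import in_silico_expectation, normalized_deviation
>>> from repeatscape.comparative import additivity_report
>>> from repeatscape.reference import genome_size_summaries, repeat_proportions, POLYPLOIDS

>>> in_silico_expectation(0.710, 0.738, 2.865, 3.52)   # parental total repeats
0.7254...       # additive expectation: 72.5% of an additive allotetraploid

>>> rep = additivity_report(repeat_proportions(), genome_size_summaries(),
...                         "fuc", "inc", list(POLYPLOIDS))
>>> rep["amounts_1c_gbp"].loc["Total repeats", ["fuc", "inc"]].round(2)
fuc    2.03    # Gbp of repeats in the maternal 1C genome
inc    2.60    # ... and the paternal — the larger genome carries more repeats
>>> (rep["amounts_2c_gbp"].loc["MITE-like", ["fuc", "inc"]] * 1000).round(1)
fuc    206.3   # Mbp of the MITE-like tandem repeat (2C) — >170 Mbp more
inc     35.2   # than in the paternal diploid
>>> rep["max_polyploid_diff_2c_gbp"]["Total repeats"].round(2)
1.24            # Gbp total-repeat spread among the allotetraploids (pra vs pur)
```

The analysis drivers under `analysis/` run the same computations as scripted
narratives and write their tables to `results/`:

```sh
python analysis/01_genome_sizes.py --seed 1     # cytometry summaries, additive CI, t tests
python analysis/02_repeat_arithmetic.py         # amounts and additivity report
python analysis/03_synthetic_pipeline.py --seed 1   # full simulated comparative run
python analysis/04_parental_bias.py             # origin/deviation classes per lineage
```

`analysis/03_synthetic_pipeline.py` simulates the full study design (two
parents, an additive polyploid, a 4×-MITE "intermediate-age" polyploid, and a
3×-MITE polyploid; ~10⁵ read pairs), then preprocesses, clusters, annotates
and classifies — and scores every estimate against the simulator's ground
truth. Typical output: all 8 families recovered within 3 binomial SE, the
MITE-like cluster classified maternal-larger and retained with deviation
≈ +0.65 in the 3× polyploid (the additive prediction is (3−1)/3 ≈ 0.67,
slightly diluted because amplification grows the genome it is measured
against), and no additive family retained.

## Cluster table format

TSV, one row per cluster: `cluster_id`, `lineage`, one proportion column per
species, and `in_silico`. Externally produced comparative cluster tables in
this shape can be ingested directly by `comparative.flag_deviating_clusters`.
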