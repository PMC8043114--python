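# bcellmap

Downstream analysis of label-free quantitative (LFQ) proteomics across
maturation-ordered human B-cell populations — naive B cells,
centroblasts (CB), centrocytes (CC), memory B cells and plasma cells
(PC) — with integration against a paired transcriptome. The package is
aimed at proteomics bioinformaticians who have normalized protein
abundance tables (e.g. from Progenesis-style LFQ quantification) and
want a reproducible, tested implementation of the classic
presence/absence + differential + integration workflow.

## What it computes

**Consensus proteome maps.** A protein is called *present* in a
population only when detected (intensity > 0) in **every** replicate.
On the resulting binary matrix the package computes exact-membership
(UpSet-style) class counts, raw intersections, per-population exclusive
proteins, pairwise presence differences, and a population dendrogram on
binary profiles (Euclidean distance, average linkage).

**A zero-propagation differential screen.** Zeros mean true absence: if
any replicate of a population reports 0, the whole population is zeroed
for that protein; proteins absent everywhere are removed. Per protein,
on y = log2(x + c):

- one-way fixed-effects ANOVA across populations
  (F = MS_between / MS_within), with Benjamini–Hochberg adjustment
  across proteins;
- Welch t-tests for all population pairs;
- max fold change = max over pairs of (larger mean / smaller mean) on
  raw-scale population means, reported as infinite (and flagged) when
  the smaller mean is 0.

Downstream summaries: per-protein z-score profiles
(z = (m − m̄)/s, sample SD), argmax/argmin population distributions,
protein-family and per-chromosome mean profiles, heatmap dendrogram
orderings, PCA of samples, and SOM clustering of z-profiles (default
5 × 1 grid → five profile clusters).

**Transcriptome screen.** Per gene: one-way ANOVA, Bonferroni
correction across genes, and Tukey HSD (studentized range;
Tukey–Kramer when unbalanced) for the survivors, plus a cross-omics
overlap report against the protein screen.

**Proteome–transcriptome integration.** Replicate means for IDs
detected in all replicates, protein↔transcript matching through an ID
map, per-population log10 P/T ratios, DBSCAN clustering of z-scored
ratio profiles (with an epsilon sweep over the k-distance curve), and
plot-ready Circos-style track tables per chromosome.

**Over-representation analysis.** One-sided hypergeometric tail test of
ID lists against GMT gene-set collections with BH correction.

**Synthetic paired-omics generator.** Log-normal intensities with
planted population-specific proteins, planted log2-scale differential
effects, intensity-dependent (missing-not-at-random) dropout, a
depth-thinned PC proteome, and a correlated 4-population transcriptome
— with a ground-truth manifest, so the whole pipeline is testable with
no external data.

## Worked example

```python
import numpy as np
from bcellmap import ScreenParams, SimulationParams, simulate_paired_study
from bcellmap.core_io import subset_populations
from bcellmap.qualitative import consensus_presence, exclusive_proteins, membership_summary
from bcellmap.quantitative import (
    differential_screen, drop_all_absent, extremal_summary, propagate_zeros,
)

proteome, transcriptome, idmap, truth = simulate_paired_study(SimulationParams(seed=42))

presence = consensus_presence(proteome)
summary = membership_summary(presence)
print("consensus proteins:", presence.n_proteins)
print("shared by all 5 populations:", summary.intersections[presence.populations])
print("exclusive to PC:", len(exclusive_proteins(presence, "PC")))

quant = drop_all_absent(propagate_zeros(
    subset_populations(proteome, ["naive", "CB", "CC", "memory"])
))
table = differential_screen(quant, ScreenParams())
print("screened proteins:", table.n_proteins)
print("significant (ANOVA p <= 0.05):", int(np.sum(table.significant)))
print("argmax counts:", extremal_summary(table).argmax_counts)
```

prints

```
consensus proteins: 369
shared by all 5 populations: 22
exclusive to PC: 22
screened proteins: 347
significant (ANOVA p <= 0.05): 268
argmax counts: {'naive': 58, 'CB': 113, 'CC': 106, 'memory': 70}
```

Of the 400 simulated proteins, 369 pass the consensus rule somewhere;
only 22 are shared by all five populations because the PC proteome is
depth-thinned (as in real sorted-PC samples, which yield far less
protein). The planted PC-specific proteins (6% of 400 ≈ 22) come back
as the PC-exclusive set. The quantitative screen — which excludes the
depth-limited PC population — calls 268 of 347 proteins differential at
raw ANOVA p ≤ 0.05; maximal expression skews toward the
germinal-center populations (CB, CC), matching the planted
up-population weights.

## Command line

```sh
bcellmap demo --out demo_out --seed 1       # one-command synthetic run
bcellmap simulate --out study --seed 1      # write a synthetic study + truth
bcellmap run --config cfg.yaml --seed 1     # full pipeline from a YAML config
```

Every run writes TSV/JSON artifacts, `run_log.txt` and a
`manifest.json` echoing versions, seed and parameters; identical
config + seed reproduces every output bit-for-bit.

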