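# Methods

## Data model and conventions

Protein abundances are non-negative normalized LFQ intensities in a
protein × (population, replicate) grid. An intensity of exactly 0 means
"not detected" and carries quantitative meaning (zero expression); it is
never represented as NaN, which keeps the zero-propagation rule and the
consensus rule well defined. Transcript expression is a gene × sample
grid of log2-scale microarray-style units. Population labels are kept
in biological (maturation) order — naive, CB, CC, memory, PC — and that
order is the deterministic tie-break wherever one is needed.

## Qualitative stage

A protein is present in a population iff its intensity is positive in
every replicate of that population (consensus rule). Proteins present
in no population are dropped before any set algebra, mirroring the
"considered for further analysis" filter such studies apply.
Membership classes use exact (UpSet) semantics — each protein belongs
to exactly one population combination — while raw pairwise and
all-population intersection cardinalities are reported separately,
since figure captions in this literature mix the two readings.
Population dendrograms use Euclidean distance on the binary columns
with average linkage; items are pre-sorted lexicographically so
equal-distance merges resolve identically on every run and under input
permutation.

## Quantitative screen

Zero handling: within each population, one zero replicate zeroes the
whole population for that protein (idempotent by construction);
proteins zero everywhere are removed; remaining zeros enter the
statistics as zero expression.

The screen runs on y = log2(x + c) with pseudo-offset c = 1 by default.
The log transform stabilizes the multiplicative replicate variance of
LFQ data; c = 1 is negligible relative to typical normalized
intensities (~10^3) and merely keeps log2(0) finite at 0. A raw-scale
option (`log_transform=False`) is kept for closed-form worked examples.

- One-way fixed-effects ANOVA per protein, computed vectorized from
  between/within sums of squares; proteins with zero residual variance
  are flagged untestable and given p = 1.
- BH adjustment across proteins (statsmodels `fdr_bh`).
- Pairwise follow-ups are Welch (unequal-variance) t-tests by default —
  population variances genuinely differ when absence zeroes a group —
  with pooled-variance available via `equal_var=True`.
- Max fold change uses raw-scale population means, larger mean in the
  numerator; when the smaller mean is 0 the ratio is reported as
  infinite with an explicit flag rather than capped at an arbitrary
  value, so downstream filters can treat presence/absence contrasts
  deliberately.
- The `significant` flag defaults to raw ANOVA p ≤ 0.05; the BH-q and
  fold-change gates are computed alongside (`screen_filters.tsv`)
  because both thresholds are in common use and legitimately disagree.

z-profiles standardize each protein's population means with the sample
SD (ddof = 1); constant profiles get all-zero z. Argmax/argmin
assignment breaks ties by maturation order and flags them. PCA centers
features and uses full SVD; component signs are fixed by making the
largest-magnitude loading positive, so scores are reproducible.

The depth-limited PC population is excluded from the quantitative
screen by default (configurable via `quantitative_populations`): its
much smaller detected proteome would make absence calls reflect sample
yield rather than biology.

### SOM

The self-organizing map is a rectangular Kohonen grid (default 5 × 1,
i.e. five ordered profile clusters) trained online for 500 epochs with
initial learning rate 0.5, both decaying linearly; the neighborhood is
Gaussian with initial radius max(rows, cols)/2 decaying to 0.1.
Prototypes initialize from data points drawn with the run's seed, and
the presentation order is seeded, so a fixed seed gives identical maps.
These defaults are the package's own choice; the literature this
workflow comes from reports only the cluster count.

## Transcriptome screen

Genes are tested with the same vectorized one-way ANOVA on expression
values as given (already log scale). Correction is Bonferroni across
genes (min(1, p·n)), matching the conservative convention of microarray
reanalyses; Tukey HSD runs only for Bonferroni survivors, using the
studentized-range distribution with the Tukey–Kramer standard error,
which reduces to the classical balanced formula when group sizes match.

## Integration

Replicate means are taken only where detection is complete: proteome
mode keeps IDs complete in at least one population and leaves other
populations' means undefined; transcriptome mode requires completeness
everywhere. P/T ratios are log10 of the direct ratio of raw-scale means
(not a difference of log means); undefined ratios (either mean missing
or ≤ 0) are excluded *before* per-ID z-scoring. Many-to-many ID
mappings collapse to the candidate with the highest grand mean and are
flagged `collapsed` — a simple, deterministic stand-in for an external
ID-conversion service's policy.

Ratio profiles are clustered with DBSCAN on z-scored rows. Because the
target cluster count (four, in the workflow this mirrors) is known but
the radius is not, `sweep_epsilon` scans quantiles of the
min_points-th-neighbor distance curve and reports every epsilon that
yields exactly the requested count. Track export replaces genomic
coordinates with per-chromosome alphabetical ordinals: coordinates in
the original figures are display-only, and ordinals keep the files
deterministic and genome-build-free.

## Over-representation analysis

One-sided hypergeometric tail, P[X ≥ k], per set, after intersecting
sets with the universe; BH across tested sets. The default universe is
the consensus-filtered protein list of the analysis at hand, not a
whole annotation database — enrichment against an inflated universe
overstates significance. Both the universe and the correction are
configurable.

## Synthetic data generator

The generator emulates the study design the pipeline targets: 5
populations × 5 proteomics replicates and a paired 4-population × 6
replicate transcriptome (PC yields too little protein for quantitative
comparison, and the paired transcriptome lacks PC).

- Intensities are log-normal: protein i draws a natural-log baseline
  mean from Normal(8, 1.2) — i.e. median intensity ≈ 3·10^3 with a
  realistic two-orders-of-magnitude abundance spread — and replicates
  scatter with SD 0.35 (~35% CV, typical LFQ reproducibility). The
  between-protein and within-replicate scales are separate parameters
  because a single spread cannot represent both.
- Differential proteins (default 25%) add effect_size_log2·ln 2 = 2
  log2-units to the up-population's log mean. The default
  up-population weights (naive 3%, CB 48%, CC 36%, memory 13%) follow
  the observed skew of maximal expression toward germinal-center
  cells; `effect_mode="paired"` instead plants the effect in CB+CC or
  naive+memory jointly, reproducing the germinal-center similarity
  structure.
- Population-specific proteins (defaults from ~0.4% for naive up to 6%
  for PC, the magnitudes of real exclusive proteomes) are zero outside
  their home population.
- Dropout is intensity-dependent: a nonzero value v is lost with
  probability logistic(slope·(ln midpoint − ln v)), midpoint 150,
  slope 1 — low-abundance proteins are preferentially lost
  (missing-not-at-random), the mechanism behind consensus absence.
- PC depth thinning removes each non-PC-specific protein from the PC
  columns with probability 1 − pc_depth_factor (default 0.15),
  reproducing the ~6:1 detected-proteome asymmetry of sorted PC
  samples. Planted PC-specific proteins are exempt so exclusive sets
  remain exactly recoverable when dropout is off.
- The transcriptome draws gene baselines correlated with protein log
  means (default r = 0.9) and shares the planted differential effects,
  so cross-omics overlap carries real signal.

What the generator does **not** emulate: peptide-level structure,
batch effects, correlated protein modules, heavy-tailed contaminants,
or isoform ambiguity. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under a clean
generative model, not robustness to every artifact of real LFQ data.

## Benchmark conditions and problem sizes

Planted-signal recovery is measured at effect 2 log2-units, 400
proteins, 25% differential, 10 seeds, with dropout off and no
population-specific proteins: intensity-dependent dropout plants
genuine absence contrasts that the truth manifest does not label
differential, so scoring them as false positives would conflate two
different planted mechanisms. Under these conditions the q ≤ 0.05
screen reaches sensitivity ≈ 1.0 at observed FDR ≈ 0.03–0.05. Null
calibration uses 500 proteins × 10 seeds (screen) and 200 random
queries × 20 sets (ORA). The acceptance script and tests use these
sizes; they complete in well under a minute each on one CPU.

## Numerical choices and degenerate inputs

- Untestable (zero-residual-variance) proteins: p = 1, flagged, never
  significant.
- t-tests returning NaN (both groups constant and equal) are reported
  as p = 1.
- BH and Bonferroni are monotone by construction; tests verify both
  against step-up / multiplication oracles.
- Linkage ties: items pre-sorted lexicographically; scipy's
  deterministic scan order then fixes the merge sequence.
- All randomness (generator, SOM, stage seeding) flows from one root
  seed through `numpy.random.SeedSequence`; derived seeds stay below
  2^31.

## Known limitations

- The screen assumes independent samples and homogeneous-enough
  variances on the log scale; severe heteroscedasticity is only
  handled at the pairwise level (Welch).
- Fold changes on raw means are sensitive to single extreme
  replicates; no outlier handling is applied beyond the log-scale
  testing.
- DBSCAN cluster count depends on epsilon; the sweep reports candidate
  radii rather than pretending a canonical four-cluster solution
  exists for every dataset.
- The ID-map collapse rule (highest grand mean) is a policy choice;
  alternatives (sum, first, all-pairs) are not implemented.
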