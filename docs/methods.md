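# Methods

This note records the models, defaults, and numerical choices behind
incitepipe, and what the synthetic benchmark does and does not
demonstrate about real data.

## The experimental design being modeled

Twelve samples — 2 stimulation conditions × 3 culture replicates × 2
antibody panels — are hashed into a single lane. Panel 1 carries
p-STAT3 and p-p65 plus a rabbit isotype control; panel 2 carries
p-ERK1/2 and p-FOS and no isotype. Condition is encoded by Hashtag1/2,
culture × panel by Hashtags 3–8. All thresholds that the analysis needs
(hash cutoffs, QC limits, isotype medians) are estimated from the data
or set in configuration.

## Synthetic data generator

The generator is first-class, tested code: it emulates the statistical
structure the analysis assumes and returns complete per-cell ground
truth (sample, doublet constituents, contaminant flag, per-target
phospho state).

**Counts.** All modalities are negative binomial (gamma–Poisson). The
real experiment gives no generative model — it measured cells — so NB is
the standard overdispersed choice, with mean and shape exposed in
`GeneratorConfig`. Per-gene relative abundances are lognormal; the
lognormal spread is root-found at construction so that the expected
detected-genes-per-cell, averaged over the lognormal library-size
distribution (CV log-sd 0.45), equals `mean_genes_per_cell`. Defaults
target the reported post-QC scale of the real dataset: 3,026 genes and
6,644 transcripts per cell over a 10,000-gene universe. When a scaled-down
gene universe cannot reach the target (the root-finder's bracket ends on
one side), the nearest achievable profile is used.

**Gene programs.** Named gene lists with a single natural-log fold
effect each, tied to truth states: resting (no positive target),
activation (p-ERK1/2 or p-FOS positive), proliferation (p-STAT3 and
p-p65 double positive), lipid metabolism (p-STAT3 positive), and a
contaminant B-cell program (*Cd79a, Cd79b, Ms4a1*). Program membership
and effects are plain configuration; overlapping programs must declare
identical effects (validation error otherwise). Program genes are pinned
to the mean baseline abundance so effects are predictable; contaminant
markers are pinned to 5% of it, since lineage markers are near-silent
outside their lineage — this is what makes a deterministic marker score a
usable stand-in for the cluster-based contaminant removal used on real
data.

**Phospho tags.** Each cell's on-panel targets draw background
NB(mean 0.5) plus, for truth-positive cells, signal NB(mean 60). The
isotype channel draws NB(mean 4, shape 8) in panel-1 cells, reproducing
group medians in the 3–5 range. The phospho-channel background mean is
deliberately *below* the isotype level: the isotype control reports the
upper envelope of nonspecific binding, and the median-subtraction rule
only recovers truth positivity when typical negative-cell counts sit at
or below the group median. Default positive fractions per condition:
p-FOS 5.42% → 86.4% (the measured stimulation shift), p-ERK1/2 8% → 78%,
p-p65 22% → 41%, p-STAT3 62% → 68% (high and stimulus-independent,
matching its IL-6-driven behaviour in these cultures).

**Hashes and doublets.** Assigned hashtags draw NB(mean 200); all others
Poisson(2). The 100× separation is a generator guarantee that makes the
two-means cutoff a faithful stand-in for visual histogram gating.
Doublet flags are the first Bernoulli draws of the structure substream
(rate 0.08 by default); each doublet is the element-wise sum of its own
profile and an independently drawn cell from a different sample, so
every default doublet is hash-detectable. Within-sample doublets are not
generated: the hash rules cannot see them, and the pipeline makes no
claim about them. Contaminants (7% default) carry the B-cell program and
no phospho signal. Mitochondrial genes receive a Beta-distributed share
of each cell's counts (mean 0.05, concentration 30).

**Randomness.** One root seed feeds named substreams (structure, RNA,
ADT, hashtag, mitochondrial share, flow noise) via `SeedSequence` spawn
keys; identical configuration is bit-identical output.

**What passing tests do not show.** The generator has no ambient RNA,
no batch or chemistry effects, no empty droplets, no within-sample
doublets, and gene programs are discrete rather than graded; recovery
results on it bound algorithmic correctness, not real-data performance.

## Demultiplexing

Cutoffs are estimated per hashtag on ln(1+count) by 1-D two-means
(midpoint of class centers, mapped back to the count scale); Otsu and
quantile methods are selectable and manual values override verbatim.
The real analysis set cutoffs visually, and does not state whether on
raw or log counts; log is used because hash counts are log-separated.
Positivity is inclusive (count ≥ cutoff) — a fixed convention. The
doublet rule is applied disjunctively as stated: a cell positive for
both condition hashes is a doublet even with a single identity hash.

## QC and contaminant flag

Pass requires genes ≥ 500, counts ≥ 500, mitochondrial fraction ≤ 0.1.
The source protocol does not state inclusivity; boundaries are inclusive
here and configurable. Pipeline order is demux → QC → contaminant flag;
the original ordering of doublet removal versus QC is unstated and does
not affect any per-cell rule, only tallies. The contaminant flag
replaces embedding + clustering with the marker score (threshold 0.5 on
mean ln(1+count) over the three markers); the run report records this
substitution.

## Isotype correction and phospho states

Medians use the mean-of-middle-values convention for even groups
(numpy's median). Since only panel 1 carries an isotype antibody, each
(culture, condition) median is computed from panel-1 cells and applied
to both panels of that group — the grouping the original text states is
culture × condition only; which counts corrected panel 2 is an
inference, surfaced here and in the run log. Medians are computed after
QC filtering (assumed; not stated in the source). The isotype channel
itself is excluded from outputs: its corrected level is ~0 by
construction. Positivity is strict (v > 0), algebraically equivalent to
raw > median — an invariant the test suite brute-forces.

## Normalization and the hurdle test

Size factors: within each cluster, library size over the cluster mean;
clusters rescaled by the median over genes (nonzero overall) of the
cluster's mean pseudo-bulk profile divided by the overall one; then a
global rescale to mean 1. Cluster labels default to `sample_id` in the
pipeline: the per-(sample × phospho-state) alternative can produce
clusters below the 2-cell floor at realistic sample sizes, and embedding-
based clusters are out of scope. Cells with zero counts are a hard error
— they belong to QC.

The hurdle test is authored here rather than delegated to an external
implementation; empirical-Bayes shrinkage and variance regularization of
heavier frameworks are deliberately omitted. The discrete part is a
ridge-stabilized (1e−8) Newton–Raphson logistic likelihood ratio — the
ridge keeps perfectly separated fits finite; the continuous part is a
Gaussian likelihood ratio over detected cells, n·ln(RSS₀/RSS₁). A
component is inestimable when detection is constant, the detected subset
is smaller than the parameter count plus one, or only one group is
detected; the remaining component is then referred to χ²(1), and genes
with no estimable component get NaN p-values and are excluded from the
BH adjustment. logFC is the difference of group means of y on the
natural-log scale (not log₂) over *all* cells of each group; direction
"up" means logFC > 0 exactly. `min_pct` (default 0.01) tests a gene if
its detection fraction reaches the threshold in at least one group. The
DEG cutoff (adjusted p < 0.05, |logFC| > 0) is configurable; the source
analysis never states its own cutoff. Null calibration is verified by a
seeded permutation simulation at 2,000 genes and 500 cells per group —
the asymptotic χ² reference is accurate there, while much smaller groups
(tens of cells) make it visibly discrete.

## Intersections and concordance

Intersection elements are (gene, direction) pairs: a gene significant up
in one contrast and down in another contributes two distinct elements
(gene-only keys are available via a flag). Signatures are ordered by
family size then lexicographically. Conservation — signature sizes sum
to the union — is a property test.

Concordance pairs per-(culture × condition, target) summaries on exact
string keys and fits simple OLS per target on two axes, sequencing as
predictor; R², the quantity of interest, is orientation-invariant.
Stimulated and unstimulated samples are pooled per target (n = 6 with
three cultures), matching the paired-sample framing of the original
comparison. Targets need ≥ 3 shared samples; fewer are skipped with a
warning. The synthetic flow table is percent = truth fraction × 100 plus
Gaussian noise (clipped to [0, 100]) and MFI = 150 + 400 × truth mean
corrected level plus noise scaled 20× — any monotone affine transform
gives the same R².

## Reagent arithmetic

The capture oligo is validated segment-by-segment (34 nt PCR handle,
7 N spacer, 11 nt barcode, 6 N spacer, 22 nt capture; 2 terminal
phosphorothioates). Conjugation: moles of linker per µL equal molarity ×
10⁻⁶; antibody moles from mass over molar mass; linker at a 1:5
antibody:linker ratio; shield protein at 12× the linker moles. The
monomer molar mass of the shield protein is not printed anywhere in the
source; 18,900 g/mol (its known sequence mass) reproduces the printed
≈ 7.5 µg per µL figure and is configurable.

## Problem sizes in the test suite

The suite exercises: demultiplexing at ~5,000 cells (RNA depth scaled
down — hashing behaviour is independent of it), positivity recovery at
1,000 cells/sample over a 60-gene universe (the ADT model does not
depend on the transcriptome), hurdle calibration at 2,000 genes × 1,000
cells, the full pipeline at 12 × 400 cells × 2,000 genes run twice for
byte-identical artifacts, and the genes-per-cell scale check at the full
10,000-gene default with a reduced cell count. These sizes are the
package's chosen benchmark conditions; the generator defaults themselves
stay at the study scale.

## Known limitations

- The contaminant flag assumes marker genes are simulated or measured
  with near-zero off-lineage background; heavily ambient-contaminated
  real data would need ambient correction first (out of scope).
- The hurdle test's χ² reference is asymptotic; with very small groups
  or near-`min_pct` genes, p-values are conservative/discrete.
- Cross-panel isotype correction is an inference forced by the panel
  design (panel 2 has no isotype), not a validated property.
- No HDF5/loom IO, no embedding/clustering, no ambient-RNA or
  model-based hashtag demultiplexing.
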