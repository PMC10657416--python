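# Methods

dropgate identifies high-quality cell- or nucleus-containing barcodes in an
unfiltered droplet RNA-seq count matrix through four data-adaptive stages,
and optionally flags dead cells among the survivors. This note documents the
model behind each stage, the tunable parameters and their defaults, the
numerical choices, what the bundled simulator does and does not emulate, and
the known limitations.

## Stage 1 — barcode-rank thresholding

Sorting barcodes by total UMI count produces the barcode rank plot: log
total UMIs against log rank. Cell-containing barcodes form a high plateau,
empty droplets an ambient plateau, and a steep cliff separates them. The
stage-1 threshold is the foot of that cliff.

Both axes are smoothed with a centred rolling mean whose bin follows the
Rice rule, b = ceil(2·n^(1/3)). Smoothing the two coordinates with the same
window (rather than only the ordinate) keeps a pure power-law curve exactly
linear; smoothing only log totals over index windows injects spurious
curvature at the low-rank end, where log-rank spacing is widest.

Continuous piecewise-linear models with k = 2…5 breakpoints are fitted to
the smoothed curve and the smallest k whose RMSE is within 1.5× of the best
RMSE is kept. At every breakpoint the angle atan(slope_left) −
atan(slope_right) is evaluated in degrees; the most negative angle — the
transition from the steepest descent to the flattest following segment —
marks the start of the ambient plateau, and the threshold rank is
floor(exp(breakpoint)). Breakpoints whose right-hand segment rises are
excluded: a rank curve is non-increasing, so such transitions can only be
smoothing artifacts. If the most negative angle is above −1°, the curve has
no meaningful transition (e.g. a single power law) and the result carries a
`weak_knee` flag. Ranks are 1-based and the threshold inclusive; ties in
total UMIs are broken by barcode id so the retained set is always an exact
prefix of a deterministic ordering.

For tractability the smoothed curve is subsampled to at most 1500 points
(evenly spaced by index) before the segmented fit; at 50k barcodes this
costs under 1% relative precision in the threshold rank. The breakpoint
search itself uses a grid of at most 200 observed x values (coordinate
descent with a nested warm start from the (k−1)-breakpoint solution, then a
bounded continuous refinement), which makes the fit deterministic and makes
RMSE non-increasing in k.

## Stage 2 — quality-metric filters

Per barcode the package computes total UMIs, detected features, and the
fractions of UMIs from mitochondrially encoded, ribosomal-protein and
protein-coding genes. Gene classes come from bundled per-organism tables
(mitochondrial gene symbols and, for human/mouse, Ensembl ids), RPS/RPL
prefix patterns for ribosomal proteins, and — when symbols are available —
a non-coding pattern table whose complement defines coding genes. With bare
Ensembl ids and no symbols, coding status is undetectable; the coding filter
is then skipped with a warning unless the user supplies a gene list.
User-supplied lists always override detection.

Filters run sequentially, each on the survivors of the previous one, so
every removed barcode has a single unambiguous fail reason:

1. **Mitochondrial fraction.** A two-component normal mixture (EM, five
   deterministic-plus-jittered restarts, tolerance 1e-8) on log detected
   features separates high- from low-coverage barcodes; barcodes with
   posterior > 0.5 for the higher-mean component are the high-coverage set.
   Candidate thresholds run from the high-coverage median mito fraction to
   1 in steps of 0.001; the number of high-coverage barcodes passing each
   candidate forms a saturating curve whose knee (maximum min–max-scaled
   chord distance) gives the threshold. A knee above 0.3 is biologically
   implausible; the fallback fits one breakpoint to log detected features
   against mito fraction — the point where library complexity collapses as
   mitochondrial content rises — and caps the result at 0.3.
2. **Coding (optionally exonic) fraction.** Barcodes more than 3×Sn from
   the median fraction are removed, where Sn is the Rousseeuw–Croux robust
   scale (nested high/low medians of pairwise absolute differences,
   asymptotic constant 1.1926, no finite-sample correction — every use
   compares multiples of Sn to deviations, so a constant factor is absorbed
   by the multiplier).
3. **Depth–complexity relationship.** Log detected features is regressed on
   log total UMIs with a three-breakpoint continuous piecewise-linear fit;
   barcodes whose residual deviates from the median residual by more than
   5×Sn are removed. The fit requires at least max(5, 2% of barcodes) data
   points per segment so breakpoints cannot be spent carving out individual
   outliers — the very points the filter must flag. An absolute floor of
   1e-8 on the deviation threshold keeps an exactly piecewise-linear
   relationship (residuals at numerical noise) from flagging anything.

## Stage 3 — expression-based cluster validation

Barcodes that pass the metric filters but carry no distinct biological
signal (ambient-profile droplets, low signal-to-noise cells) are removed by
over-clustering and per-cluster differential expression.

The top 5000 highly variable genes are ranked by binomial deviance under a
constant-proportion null (the count of gene g in barcode i is Binomial(n_i,
π_g) with π_g the pooled proportion); genes expressed at the same
proportion everywhere have deviance ≈ 0. Counts are depth-normalised to the
median depth, log1p-transformed, z-scored per gene (clipped at |z| = 10)
and decomposed by truncated SVD (30 components, deterministic start vector
and sign convention). A shared-nearest-neighbour graph (k = 20 neighbours,
Jaccard edge weights, pruning below 1/15) is clustered by
resolution-parameterised modularity (Leiden) at resolution 0.1 (shallow)
and at the highest resolution in 0.2…5.0 (step 0.2) whose smallest cluster
still has ≥ 5 barcodes (deep). Graph-isolated barcodes are attached to the
cluster of their nearest embedded neighbour.

Each deep cluster is compared against all barcodes outside its shallow
cluster (majority vote of its members), so closely related subtypes are
never used as each other's background. Genes with a nonzero count in the
union are tested by Wilcoxon rank-sum on the normalised log values; AUC,
log fold change, the percentage of barcodes expressing the gene inside and
outside, and Benjamini–Hochberg FDR are reported. Enrichment requires a
positive log fold change; the top 10 markers are ordered by FDR, ties by
AUC.

A deep cluster fails when any of the following holds: a top-10 marker is
expressed in ≥ 1 percentage point fewer of its barcodes than of the
background; the top-10 averages violate pct_in > 30, pct_out < 70 or
pct_in − pct_out ≥ 20; fewer than 1% of tested genes are significant
(FDR ≤ 0.05); −log10 of its best FDR falls below a data-adaptive threshold;
or its mean mitochondrial or ribosomal fraction exceeds the across-cluster
median by more than 3×Sn of the cluster means. The data-adaptive threshold
regresses −log10(min FDR) on the average marker percentage difference
across deep clusters and fails clusters more than 2×Sn of the residuals
below the line, with an absolute floor at −log10(0.05); it is isolated in
one function so the functional form can be swapped. The last two rules need
an across-cluster distribution and are skipped when only one deep cluster
exists.

## Stage 4 — dead-cell flagging (optional)

Dead cells that survive regular QC have more UMIs, a higher coding fraction
and a depleted ribosomal fraction than live cells. Each QC-passing barcode
is scored with fixed coefficients on four features — R and C the
arcsine-square-root transformed ribosomal and coding fractions rescaled by
2/π to [0, 1], U and F the log total UMIs and log detected features centred
over the scored set:

    score = −11.82·U + 2.08·F + 158.98·R + 18.87·C·F − 125.9·R·C

Low scores are dead-like. Initial labels come from the first knee of the
empirical distribution function of scores between the 0% and 10% quantiles
(the window grows in 10% steps while nothing is labelled); scores strictly
below the knee are putative dead. When one score gap below the knee spans
more than half the window range — a clearly bimodal window — the threshold
snaps to the upper edge of that gap, which is where the EDF's first knee
sits; without a dominant gap the chord knee itself is used. Labelling halts
(and everything reports live) when fewer than 3 or more than 10% of
barcodes would be labelled, or when no knee exists.

Labels are then refined on a 100-component SVD embedding of the top 2000
HVGs. Each of 10 independent runs performs up to 10 epochs of: selecting
embedding components with two-sided Kendall-tau p < 0.05 against the
current labels (at least 2, else the top 5 by |tau|); sampling training
labels from the previous epoch's predicted class probabilities (the initial
labels in epoch 1, which keeps their signal); jittering the selected
features with Gaussian noise at 0.1× their standard deviation; fitting an
L2-penalised logistic model whose penalty is chosen by stratified 5-fold
cross-validation of the out-of-fold deviance over a 100-point log-spaced
grid; and relabelling at probability 0.5, stopping early when labels are
stable. The ridge path is fitted in-package by damped IRLS warm-started
along the grid — the same model and selection criterion as the standard
penalised-regression CV, several times faster at this problem shape; the
fold count shrinks to the smaller class size when a class has fewer than
five members. A barcode is called dead or live only when at least 8 of the
10 runs agree; if more than 10% of barcodes lack consensus the whole run
fails and every barcode reverts to live. When no QC-passing barcode is
initially dead-labelled, the highest-scoring putative-dead barcode is
temporarily included in the refinement set and excluded from the report.

Scoring and initial labelling use stage-2 survivors; refinement and
reporting are restricted to stage-3 survivors. The score is calibrated on
whole cells, so dead-cell flagging refuses to run on single-nucleus input
unless forced.

## The synthetic-data generator

`simulate_dataset` emulates the regimes the pipeline must separate: an
ambient plateau of empty droplets (negative-binomial depth, mean 40, size
1, drawing from the depth-weighted average of the cell profiles), several
cell populations (3 types × 500 cells by default; NB depth mean 5000, size
4; 20 disjoint marker genes per type at a 12% expression share; 5% ambient
admixture), high-mitochondrial debris (150 barcodes; mito fraction
Beta(20, 20) versus Beta(2, 40) for intact cells; half the cell depth), and
a planted dead-cell population (5% of cells by default: depth ×2,
per-barcode ribosomal fraction ×0.2, non-coding share ×0.8, plus a 50-gene
death-signature block at an 8% share). Per-barcode mitochondrial,
ribosomal and non-coding fractions are beta-distributed, giving quality
metrics realistic spread — in particular, dead cells remain inside the
stage-2 coding-fraction band, as they must for stage 4 to be meaningful.
Multinomial sampling is realised as iid categorical draws accumulated into
a sparse matrix, which is distribution-identical and fast at droplet
depths.

What the generator does **not** emulate: doublets, ambient-profile
chemistry (the soup is a simple profile average), batch or cell-cycle
structure, gene–gene correlation beyond the marker blocks, and
zero-inflation beyond what the negative-binomial/multinomial hierarchy
produces. Tests passing on these simulations show that each stage's
decision rule behaves as designed under its intended signal; they do not
certify performance on any particular tissue or chemistry.

## Problem sizes used by the test and acceptance suites

The suites run at desk scale on one CPU: the default simulation (1650
cell-like barcodes + 20k empties, 2000 genes) for the planted dead-cell
recovery and determinism checks; a reduced mixed simulation (3 × 250 cells,
8k empties) across 10 seeds for the stage-3 discrimination check; 2 × 150
cells for the null (no-dead) suite; and a 2 × 220-cell simulation with 10%
dead for the subsampling sensitivity analysis (removal fractions 0.1 / 0.3
/ 0.5, six repeats each). These sizes are the package's own test-design
choice; all thresholds and rates under test are the defaults documented
above.

## Numerical choices and degenerate inputs

- Natural logarithms throughout; only ratios matter.
- Knee detection min–max scales both axes before the chord-distance
  computation, so it is invariant to affine rescaling of either axis; ties
  break to the smallest index and an (almost) collinear curve returns the
  first interior point with a degenerate flag.
- EM mixture: component sd floored at 1e-4× the data sd; a collapsed
  mixture (indistinguishable means or vanishing weight) makes the mito
  threshold treat all barcodes as high-coverage, with a warning.
- Zero-UMI barcodes are dropped at load: they carry no information and
  break the log transforms.
- Matrix orientation is genes × barcodes; a transposed MTX file is detected
  by comparing dimensions with the id-list lengths, with an explicit
  override flag.
- Exon/intron fractions are accepted only as user-supplied annotations —
  they require alignment-level information absent from a count matrix —
  and reuse the coding-fraction rule (median ± 3×Sn).
- All randomness flows from one master seed (SeedSequence spawning); every
  stage is bit-reproducible for a fixed seed, and the run report contains
  every chosen threshold, the seed and the package version.

## Limitations

- Stage 3 assumes biological heterogeneity: on a homogeneous sample (one
  pure cell line) the clustering-based validation cannot find distinct
  signals and may reject valid barcodes.
- The dead-cell score coefficients are fixed constants taken as given; the
  package deliberately does not re-derive them, and their calibration may
  not transfer to chemistries or species far from their training regime.
- The data-adaptive minimum-FDR rule (stage 3, rule d) is one realisation
  of a dependence between marker specificity and significance; its exact
  functional form is a design choice, kept behind a single function.
- Automatic gene-class detection covers the common organisms and id
  schemes; anything else needs user-supplied gene lists.
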