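# Methods

This note documents the statistical procedures the package implements,
the defaults and why they were chosen, what the synthetic-data layer
does and does not emulate, and the numerical conventions that make the
pipeline deterministic.

## Study design and vocabulary

The package targets cohorts of the inducible α-synuclein mouse design:
conditions `synON` (lifelong transgene expression), `synlateON`
(expression induced late, around 5 months) and `synOFF` (no
expression), sampled at ages 6M, 16M and 24M.  Contrasts are ordered
pairs of condition-by-age groups written `test_vs_reference`.  Eight
named contrasts drive the signature logic: the four symptomatic ones
(`synON`/`synlateON` vs `synOFF` at 16M and 24M), the pre-symptomatic
`synON6M_vs_synOFF6M`, and the three aging contrasts within `synOFF`
(24M vs 6M, 16M vs 6M, 24M vs 16M).

## Quality control and pseudo-bulk differential testing

Cell-level filters are removal rules with strict boundaries (a cell at
exactly the threshold is kept): nUMI < 2500, nGene < 1500,
mitochondrial fraction > 3%, ribosomal fraction > 1.5%, and
log10(nGene)/log10(nUMI) < 0.85.  The last metric is the standard
genes-per-UMI complexity score; the naive ratio log10(nGene/nUMI)
cannot be meant by a 0.85 threshold since it is non-positive for every
cell.  All thresholds are configurable (`QCThresholds`).

Cell numbers are balanced across batch-by-condition groups before
pseudo-bulking: every group is subsampled (uniformly, without
replacement, seeded) to at most ⌊smallest group × 1.5⌋ cells.  Groups
are trimmed, never inflated, and a declared group with zero cells is
an error rather than a silent pass.

Pseudo-bulk counts are per-sample sums.  Genes are kept when they have
counts ≥ 3 in ≥ 3 samples — read as raw pseudo-bulk counts, since the
filter precedes normalization — and when their symbol does not match
the ribosomal/mitochondrial prefixes `mt-`, `Rps`, `Rpl`, `Mrps`,
`Mrpl` (case-insensitive).

The built-in differential test is a per-gene negative-binomial GLM
with a log link, median-of-ratios size factors as offsets, and a Wald
test on the condition coefficient.  The NB dispersion is a pooled
method-of-moments estimate from within-design-group means and
variances of normalized counts, floored at 1e-8 (near-Poisson genes
fall back to a Poisson family).  P-values use a t reference with
residual degrees of freedom rather than the normal, which keeps the
type-I error of the test at or below nominal in the small-sample
designs it is meant for (measured ~0.03 at nominal 0.05 on null
simulations with 6 vs 6 samples).  Genes that are all-zero in both
arms are excluded and logged; genes where the GLM fails to converge
fall back to a Welch t-test on log2 normalized counts and are logged.
Multiplicity is controlled by Bonferroni–Holm at α = 0.05.  Surrogate
variable analysis and p-value recalibration are intentionally not
reproduced: covariates are user-supplied sample columns, and the
downstream logic accepts externally produced tables (including a
DESeq2 route via `method="deseq2"` when pydeseq2 is installed, which
the test suite uses as an independent cross-check).  No fold-change
shrinkage is applied; infinite ratios in the fallback path use a 0.5
pseudo-count.

Residual batch effects are handled by testing batch as a contrast and
deleting its significant genes from contrasts declared confounded.

## Signature set logic

Let S(c) be the Holm-significant genes of contrast c.  With
I16 = S(on16) ∩ S(late16) and I24 = S(on24) ∩ S(late24), the four-way
intersection I = I16 ∩ I24 is partitioned by 6-month presence:
PD Signature = I \ S(on6), PD Beginning = I ∩ S(on6).  Directions are
recorded from the lifelong-expression 24-month table.  Requiring equal
log2FC signs inside the four-way intersection is available as a flag
but off by default, since the defining criterion is shared presence;
the aging rule, by contrast, always enforces direction: a gene is in
the Aging Signature iff it is significant in 24M-vs-6M and
significant *with the same sign* in 16M-vs-6M or 24M-vs-16M, and not
significant with the opposite sign in either.  "Present at 6M" uses
the same padj < 0.05 criterion as every other table.

## PIDC network inference

Expression is discretized per gene; the default is uniform-width
binning with a Sturges bin count ⌈log2(n_cells) + 1⌉, a deterministic,
dependency-free stand-in for the original algorithm's discretizer
(Bayesian blocks is available as an option).  Constant genes occupy a
single bin, carry no information, and are excluded with a report.

All information measures are plug-in (maximum-likelihood) estimators
in bits.  For sources X, Z and target Y the Williams–Beer redundancy
is Red = Σ_y p(y) · min_S I_spec(S; y) with
I_spec(S; y) = Σ_s p(s|y)[log2 p(s|y) − log2 p(s)]; unique
information is Uniq_X = I(X;Y) − Red, clipped at zero against
floating-point error.  These satisfy Uniq + Red = I exactly and
0 ≤ Red ≤ min(I(X;Y), I(Z;Y)).

The proportional unique contribution of a pair sums over all third
genes: u(X,Y) = Σ_Z [Uniq_X(Y|Z) + Uniq_Y(X|Z)] / I(X;Y), with a zero
term when I(X;Y) = 0.  Confidence calibration uses each gene's
empirical CDF over its own pair scores (ties take the maximum rank
fraction) instead of a fitted gamma — fewer assumptions and exact at
the tens-of-genes scale this stage is designed for; the confidence of
an edge is the sum of its two endpoint CDF values, in [0, 2].  The
top ⌈0.10 × n_pairs⌉ edges are selected, with ties at the cutoff
broken by higher raw PUC and then lexicographic gene pair so results
are reproducible.  The O(G³) triplet cost is accepted because the
stage runs on signature genes only (tens of genes); 20 genes × 2,000
cells takes about two seconds.

## Network construction and central regulators

Interaction databases are undirected weighted edge lists; the STRING
dialect's combined scores (0–999) are divided by 1,000 and filtered
strictly above 0.600, duplicates across sources are merged keeping the
maximum score and the union of source tags.  The constructed graph
contains every database edge between two seed (signature) genes plus,
for every seed pair joined by a length-2 database path, the
intermediate gene and both its edges — at most one interconnecting
gene, and never an edge between two interconnecting genes.

Over-connectivity uses edge sampling: drawing the constructed graph's
n edges from the database's N edges, the probability that a gene with
database degree K shows degree ≥ k is the upper hypergeometric tail
P(H ≥ k), H ~ Hypergeom(N, K, n).  (A node-endpoint-sampling
parameterization is conceivable; the edge-sampling reading keeps k ≤ K
structurally true since graph edges are database edges.)  Holm
adjustment runs across all tested network genes; ranking is by
adjusted p, then raw p, then higher degree, then gene name.  The top
20 ranked genes are the disease central regulators; for the aging
workflow, genes in the KEGG oxidative-phosphorylation set or any GO
cellular-component set whose name contains "mitochondrial",
"respiratory chain", "respirasome", "NADH" or "oxidoreductase" are
collapsed to a single "Mitochondria" label *before* the top 40
non-mitochondrial genes are selected, in that order.  Annotation sets
are supplied as GMT files; there are no live database queries.

## Topic interactions

With a curated gene→topic assignment (an input, not computed), the
observed count of network edges joining two distinct topics is
compared to its distribution under 10,000 uniform permutations of the
assignment over genes (the label multiset is preserved on every draw;
network genes without a label are pooled as "Unassigned" and
reported).  P-values are one-sided toward over-connection and use the
add-one rule p = (1 + #{count_perm ≥ count_obs}) / (1 + n_perm), so
the score −log10 p is always finite.  Each topic keeps its two
highest-scoring partners (ties by higher observed count, then name);
topics with fewer than two assigned genes are dropped before
selection.

## Proteomics

Intensities are log2-scale with explicit missing values.  Filtering
keeps proteins detected in at least two samples of *each* batch and in
at least 75% of replicates of at least one condition (both thresholds
inclusive, matching "at least"/"minimum of").  For a two-condition
comparison, a protein is MNAR when one arm is ≥75% detected and the
other ≥75% missing (inclusive at exactly 75%), MAR for any other
pattern with missing cells, and complete otherwise.

MAR cells are imputed by k-nearest-neighbour averaging over proteins
(k = 10, Euclidean distance on shared observed samples, via
scikit-learn's nan-aware imputer).  MNAR cells are drawn from a
Gaussian centred at the per-sample 1% quantile of observed intensities
with SD equal to the median per-protein SD — the conventional MinProb
parameterization, configurable and logged.  Observed cells are never
altered, and imputation is deterministic under its seed.

Differential testing is a per-protein ordinary-least-squares linear
model, intensity ~ condition + sex + batch, with a t-test on the
condition coefficient and Holm control at 0.1.  Empirical-Bayes
variance moderation is deliberately not reimplemented; externally
moderated tables can be supplied instead.  A consequence worth
knowing: with four replicates per arm the residual variance has few
degrees of freedom, so at proteome-scale multiplicity the unmoderated
test is substantially less powerful than a moderated one — the power
checks in the test suite therefore run on desk-scale panels (30
proteins), where a planted 2-unit shift is detected at Holm-adjusted
0.1 in ≳95% of cases.  A rank-deficient design raises an error naming
the collinear columns, and an explicit sample-exclusion hook
(`ProteinMatrix.drop_samples`) covers data-specific removals such as
replicates forming a spurious subcluster.

## Cross-species scoring

The module score reimplements the classic binned-control statistic:
genes are ranked by average expression into 24 equal-count bins; each
signature gene contributes 100 control genes sampled from its bin
(excluding signature genes, with replacement when a bin is small); the
per-cell score is the mean over signature genes minus the mean over
the pooled controls.  Bin count and control-pool size are the
algorithm's conventional defaults, configurable.  Group differences
are tested on per-sample mean scores with an exact two-sided
rank-sum test (exact up to 25 samples per arm, tie-corrected normal
approximation beyond).

For cross-dataset effect-size comparison, each dataset's log2 fold
changes are rescaled symmetrically so the most extreme value maps to
±4 (x → x·4/max|x|, applied always, so every dataset's range is
calibrated; clipping is available as an alternative mode).  Gene
symbols are matched case-insensitively across species, and a gene is
concordant when its sign is identical and nonzero in every dataset.
A convenience rule flags user-supplied clusters as GABAergic when all
four markers (GAD1, GAD2, SNAP25, SYT1) have above-median mean
expression; it is a helper, not a clustering method.

## Synthetic data

Counts: each cell draws a standard-normal latent value per gene; genes
sharing a planted edge share a latent factor whose weight is the
coupling strength c ∈ [0, 1], so the latent correlation of the pair is
exactly c (coupling 1 duplicates the factor; per-gene total coupling
is capped at 1).  Latents map through the Gaussian CDF and the
negative-binomial quantile function with per-group means — baseline
`nb_mean` times 2^log2FC for planted effects in a contrast's test arm,
times batch multipliers for planted batch genes.  The NB size
parameter defaults to 10 (variance = μ + μ²/10).  This copula design
gives tunable, discretization-robust dependence without simulating
transcriptional kinetics, and makes planted fold changes land on the
pseudo-bulk scale (a planted log2FC of 2 yields pseudo-bulk mean
ratios of ~4).  Cohorts default to 4 animals per condition-age group
with batch and sex alternating on different periods so the two
covariates are never collinear.

What the generator does *not* emulate: UMI sampling, ambient RNA,
doublets, cell-type mixtures, library-size variation beyond NB noise,
and mean–dispersion trends.  Passing tests therefore demonstrate the
correctness and calibration of the downstream procedures under their
stated assumptions, not robustness to those artifacts.

Ready-made differential tables (`simulate_dge_tables`) realize an
overlap design exactly: requested genes are significant with the
requested sign, everything else is null with log2FC ~ N(0, 0.1) —
contradictory signs pass through verbatim so rule behaviour can be
probed.  The mock interaction database contains every true edge with a
score above 0.600 plus the requested number of decoy non-edges with
scores from a chosen law.  Proteomics intensities are Gaussian on the
log2 scale (base ~N(25, 2) per protein, replicate noise SD 0.3, a
+0.3 batch shift); MNAR is planted by left-censoring a flagged
(protein, condition) below its 75th within-condition percentile, MAR
by Bernoulli masking independent of intensity, with MNAR-flagged
proteins exempt from MAR masking so planted labels stay unambiguous.

One global seed is split into per-operation substreams (hashing the
operation name into a seed sequence), so identical configurations are
bit-reproducible and operations are insensitive to call order.

## Numerical conventions and determinism

- 0·log 0 := 0 throughout; MI and PID components are clipped at zero
  against rounding at the 1e-12 scale.
- All ranking ties break deterministically (documented per stage),
  and every stochastic operation takes an explicit seed.
- Holm adjustment is used everywhere multiplicity is controlled;
  adjusted p-values never fall below raw ones.
- Degenerate inputs (empty QC output, empty databases, all-zero
  fold-change vectors) warn rather than fail when a sensible empty
  result exists, and raise with a named culprit when not (empty arms,
  rank-deficient designs, proteins with no observed values).

## Problem sizes used in the checks

The test suite and the acceptance script run at desk scale, chosen so
each stage's property is measurable with comfortable margins:
20 genes × 2,000 cells for network recovery, 6-vs-6 samples × 500
cells for differential power, 100-gene null panels for calibration,
30-protein panels for proteomics power, and 10-gene universes for the
1,000-fold set-logic enumeration.

## Known limitations

- The PIDC stage promises the method's structure (PID with
  Williams–Beer redundancy, PUC, CDF confidence), not score-identical
  replication of any particular legacy implementation, whose
  discretizer and estimator options are not part of this package.
- The hypergeometric edge-sampling universe is one defensible reading
  of degree-vs-database over-connectivity; node-endpoint sampling is
  not implemented.
- The unmoderated proteomics t-test loses power at proteome-scale
  multiplicity (see above).
- Identifier mapping across species is by case-insensitive symbol
  only; no orthology resolution.
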