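# Methods

`sctme` reimplements, as a tested library, a complete analysis of paired
tumor/adjacent-normal single-cell RNA-seq: quality control, clustering,
marker-score cell-type annotation, expression-based CNV calling of
malignant cells, pseudotime analysis of myeloid reprogramming with
transition-state genes, gene-set enrichment, ligand-receptor crosstalk and
a co-regulatory network. A synthetic-data generator plants ground truth
for every stage so the whole chain is verifiable without any download.

## Quality control

Cells are kept when they detect at least 200 genes and carry at most 40%
mitochondrial UMIs; each removal is attributed to the first failing rule.
Genes are kept when expressed (count > 0) in at least 5 cells, recomputed
after cell removal. "Detected"/"expressed" means count > 0 throughout; no
separate detection threshold exists. The boundary at exactly 200 genes is
kept by default (cells *below* 200 are discarded); a strict-greater variant
is available via `strict_min_genes` because the two natural readings of
the rule differ only at that boundary.

## Normalization, covariates, variable genes, clustering

The log layer is `ln(1 + count * 10000 / cell_total)`; the scale factor is
the droplet-data convention and configurable. Technical variation is
removed per gene by OLS on total UMIs and mitochondrial fraction
(intercept included; constant covariates are dropped with a warning).
Variable genes are selected by binning genes into 20 mean-expression bins
and z-scoring the log dispersion (variance/mean) within bins; kept genes
satisfy `0 < mean <= 8` and `z >= 0`. Bins with fewer than two genes get
z = 0.

Clustering scales the variable-gene residuals to unit variance (clipped at
±10), takes 30 principal components (exact SVD), builds a shared-nearest-
neighbor graph (Jaccard overlap of k-nearest-neighbor sets, pruned at
1/15) and partitions it with Leiden modularity at resolution 1.0. The
neighbor count defaults to `2 * sqrt(n_cells)` (floor 15): with the
k = 15 convention the modularity partition misplaces boundary cells that
the PC-space structure resolves, and the denser graph recovers them
without changing the partition on well-separated data. t-SNE (seeded) or
the first two PCs provide 2-D coordinates for reporting only.

## Cell-type annotation score

For clusters 1..N and marker sets G_t (types 1..T),

    C_i(G_t)  = sum_{j != i} C_ij(G_t)
    C_ij(G_t) = sum of log2FC_ij(g) over markers g in G_t
                with BH-adjusted p_ij(g) < 0.05

where log2FC and p come from a per-gene negative-binomial likelihood-ratio
test between clusters i and j (below). The sum is signed as the formula
reads — a marker *depleted* in cluster i subtracts from the score; a
`positive_only` switch restricts to elevated markers for users who prefer
the conservative variant. BH adjustment is per pairwise test. Each cluster
is assigned `argmax_t C_i(G_t)`; ties are flagged ambiguous and broken by
the largest single pairwise contribution, then type name.

## Negative-binomial differential testing

All differential tests share one engine: counts are modeled as
NB(mean = s_c * lambda_group, variance = mu + alpha * mu^2) with
library-size offsets s_c (total UMIs / median). Per-gene dispersion is a
method-of-moments estimate shrunk toward a rolling-median trend over
mean-ranked genes with weight n/(n+50). Group rate MLEs come from a
Newton iteration on the scalar score equation, vectorized across genes, so
a pairwise test over thousands of genes takes milliseconds. Significance
is a likelihood-ratio chi-square (df = number of groups − 1) with BH
adjustment over the genes tested; genes all-zero in the compared cells are
excluded from testing and from the BH denominator. log2 fold changes are
computed from the fitted rates expressed per 10,000 UMIs with a
pseudocount of 1 on that scale — mild for expressed genes, shrinking
toward zero for barely detected ones. On a planted two-group comparison
the engine agrees with edgeR's exact test in development cross-checks
(fold-change correlation > 0.99, top-gene overlap complete); edgeR is not
a dependency.

## CNV inference and malignancy calls

Genes are ordered by chromosome and position; per-cell window scores are
the mean of log expression over 200-gene windows advanced by 50 genes
(step chosen for 4x overlap; the window size is the published value).
Before averaging, the log layer is centered twice: per gene on the mean
over reference cells (default: all normal-tissue cells), and per cell on
the autosomal mean. The second centering removes global per-cell
depth/detection shifts which otherwise make every chromosome's score
distribution appear bimodal and destroy calling specificity; only regional
deviations survive it.

Each window is tested by a likelihood ratio of a two-component
tied-variance Gaussian mixture (EM, k-means init, 10 restarts, tol 1e-6,
variance floor 1e-4) against a single Gaussian; p-values use chi-square
with df = 2 (one extra mean, one extra weight). The mixture boundary makes
this df approximate; null simulations show the test slightly conservative
to mildly anti-conservative within the slack the calling thresholds
absorb. BH across windows defines significant regions at adjusted
p < 0.05. In each significant region the component nearer the
reference-cell mean is neutral; cells assigned (posterior argmax) to the
other component in at least one region are putative malignant cells.
Windows where the reference cells split more than 40/60 between components
carry no usable polarity and are excluded.

## Trajectory and transition-state genes

Ordering genes are the union of per-cluster one-vs-rest NB tests (adjusted
p < 0.05), each cluster contributing up to 50 genes not already
contributed — with two clusters the one-vs-rest tests mirror each other,
and without this rule the budget would collapse to 50 genes total.

Cells are embedded by PCA to two dimensions on the standardized ordering
genes. Topology comes from a principal tree: k-means centroids
(k = max(sqrt(n)/2, 10)), a minimum spanning tree over them, projection of
cells onto the nearest edge, and states defined as maximal degree-2 chains
between branch/leaf nodes. Rooting is two-pass: the state with the highest
root-population enrichment (count x purity of the designated root cells,
default CD14+ monocytes from normal tissue — the mass weighting stops a
small pure spur from outvoting the true root segment) is the root state;
pseudotime is then recomputed from the root end.

Pseudotime itself is arc length along a principal curve: the cells ordered
by the first principal component (oriented so root cells sit early),
smoothed by a centered rolling mean (span 25% of cells, ends trimmed), and
every cell projected onto the resulting polyline. A raw geodesic on the
centroid MST was evaluated during development and discarded: the MST
zigzags across the embedding's noise width and caps rank recovery of a
planted linear ordering around 0.85, while the principal curve tracks the
first component's 0.91+ on every seed tested. This is the same resolution
the Slingshot lineage-curve design uses for cluster-MST trajectories.

Branch fates are named from annotation: the leaf state richest in the fate
population (M2 macrophages) is AT1, the runner-up AT2. For reporting, a
path's cells are all cells except those on a substantial alternative
branch — exclusive states of another leaf holding >= 10% of cells *and*
spanning >= 30% of the pseudotime range; small end-fan spurs of the
embedding remain on the path. CD141+ DC cells are excluded from trajectory
input by the pipeline default, matching the lineage argument for analyzing
CD1c+ DC but not CD141+ DC.

Two gene-level tests follow. The state test is the NB LRT with the state
factor (states under 3 cells merge into their pseudotime-nearest
neighbor). The transition test fits, per gene, an NB GLM on a natural
cubic spline basis of pseudotime (df = 3, knots at quantiles, the common
default for an unspecified smooth) against an intercept-only model. It
runs over all trajectory cells by default, as the smooth-pseudotime test
it mirrors does; a caller analyzing a genuinely branched trajectory can
name the alternative fate to exclude its exclusive states. Automatic
geometric branch exclusion is deliberately not applied — on linear data
the embedding's noise forks would cut real path cells and cost most of the
detection power. Dispersion is estimated after coarse pseudotime binning
so genuine trends do not inflate it; chi-square df = 3, BH across genes. Transition-state genes
satisfy raw p < 0.005 AND FDR < 0.05; direction is the sign of the
Spearman correlation between the fitted curve and pseudotime, with
|rho| < 0.2 flagged ambiguous.

## Enrichment, crosstalk, network, subsets

Gene-set enrichment is the one-sided hypergeometric tail P(X >= k) with BH
across the collection's sets, significance at adjusted p < 0.05; the
universe defaults to the genes surviving the gene filter (the choice is
exposed because analyses differ on it). A presentation column reproduces
the -log10(adj p)/10 bar-plot transform.

A ligand-receptor interaction from type A to type B exists when at least
one A cell expresses the ligand and at least one B cell the receptor
(count > 0); `min_count` generalizes the rule. The receptor set of
interest for sourcing summaries is user input (the original upstream-
regulator inference used a proprietary tool and is out of scope);
summaries count distinct ligands per source type with percentages over the
ligand union.

The co-regulatory network regresses each target gene on candidate
regulator expression with an ExtraTrees ensemble (500 trees by default,
max_features = sqrt, per GENIE3 convention); importances are nonnegative
and sum to one per target; the hub is the regulator with the largest
summed outgoing importance. Epithelial subsets split on cluster-level
ligand expression: a cluster joins subset 1 when every ligand of the given
set is detected in at least 25% of its cells (the fraction is an invented,
configurable rule — the source analysis states no quantitative criterion);
subset DE reuses the NB engine with significance at adjusted p < 0.01 and
|log2FC| > 1.

## Synthetic data

The generator emulates the structure the pipeline assumes. Expected counts
are `mu_gc = L_c * w_gc / sum_g w_gc` with library sizes log-normal around
3,000 UMIs (CV 0.3; within the study's per-cell UMI range) and relative
rates w composed in log2 space: a log-normal gene baseline (sd 1.0, giving
the right-skewed detection profile QC assumes); +2 log2 for a type's 10
markers in its home cells (4-fold, the regime the recovery checks
specify); ±2 log2 x pseudotime for the 50 up and 50 down transition genes;
log2(dosage) for CNV-region genes in malignant cells (malignant cells
drawn only from tumor-tissue epithelium); +3 log2 in home types and −12
log2 elsewhere for ligand/receptor genes (type-exclusive channels by
construction); and regulator-activity terms (activity ~ N(0,1) per TF per
cell, echoed by the TF's own transcript and by each target's mean over its
parents). Counts are gamma-Poisson with a shared dispersion alpha = 0.3
(variance mu + alpha mu^2), Poisson in the alpha -> 0 limit. Thirteen
designated MT genes take a Dirichlet-perturbed 5% share of each good
cell's library, and a planted low-quality block (30 cells by default)
combines ~100-UMI libraries with >40% mitochondrial share so the QC
filters remove exactly that block.

Role genes — markers, the transition program, TFs and their targets —
draw their baselines from the folded (upper-half) log-normal. They model
transcripts that are well expressed *by construction*: marker and
transition genes are, in the emulated study, themselves the output of
differential screens, and a near-silent TF transcript carries no activity
readout. Without the fold, a fraction of planted "ground truth" genes draw
baselines of a few total UMIs and are unrecoverable by any estimator,
which would make recovery tests measure the lottery of the baseline draw
rather than the pipeline.

The transition program size (50 up + 50 down at effect 2 log2) reflects
the large gradual programs the monocyte-to-M2 literature describes; the
trajectory types default to a monocyte root with an M2 fate (a CD1c+ DC
fate joins for two-branch simulations), with normal-tissue cells
concentrated early (80% drawn from [0, 0.3]) so the root is
normal-enriched. Tissue composition is type-biased (M2 enriched in tumor,
monocytes in normal), matching the compositional shifts the study design
concerns.

What the generator does not emulate: doublets, ambient RNA, patient batch
effects, gene-gene correlation beyond the planted programs, UMI saturation
and isoform structure. Passing recovery tests therefore demonstrates the
pipeline's correctness on data satisfying its own model assumptions, not
robustness to the full noise anatomy of real droplet data.

## Problem sizes and determinism

The shipped tests and the acceptance script run the stages at roughly
0.4-1.2k cells and 2k genes per dataset — large enough that the recovery
statistics stabilize (ARI and AUROC margins > 0.05 above their thresholds)
while the full suite stays interactive. Every stochastic component
(generator, k-means, EM restarts, Leiden, tree ensembles, t-SNE) takes an
explicit seed; two runs with the same config and seed produce
byte-identical outputs, which the pipeline manifest verifies via content
hashes.

## Known limitations

The enrichment-score sum is signed exactly as the defining formula reads;
whether depleted markers *should* subtract is genuinely ambiguous, hence
the `positive_only` switch. The chi-square df = 2 for the mixture LRT
ignores the boundary non-regularity. The principal-curve pseudotime
assumes the trajectory is monotone along the leading principal component
of the ordering-gene embedding; strongly curled trajectories would need
the full iterated principal-curve machinery. CNV calling reports window-
granularity regions, not integer copy numbers or breakpoints. The pipeline
performs no batch integration across patients (deliberately, matching the
plain-concatenation design it reimplements).
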