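# Methods

This note documents the models and procedures ovatlas implements, the
parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Data model and ingestion

Count matrices are sparse cells×genes integer matrices with unique
barcodes and stable gene identifiers; symbols are display-only.
MatrixMarket triplets are accepted in either orientation — whichever
axis matches the barcode file becomes the cell axis — so matrices
written genes×cells (the common convention for 10x-style exports)
load identically. Mitochondrial genes are flagged by symbol prefix
(`mt:`, the FlyBase convention; configurable). All percentages are on
a 0–100 scale.

## QC filtration

Per cell: `n_genes` (genes with count > 0), `n_umi` (total counts),
`pct_mito` (percent of counts on flagged genes; 0 for an empty cell).
Defaults: keep cells with 775 ≤ n_genes ≤ 2,200, n_umi ≤ 18,000,
pct_mito ≤ 1%. The phrase "more than 2,200 genes and 18,000 UMIs" is
grammatically ambiguous between one joint condition and two bounds; we
apply the two upper bounds independently (a cell exceeding either is
removed), which is the conservative reading and common practice, and
expose `upper_joint=True` for the conjunctive reading. The removal
report counts every violated bound per cell, so reason counts can sum
to more than the number of removed cells.

## Normalization, HVGs, cell cycle, scaling

Log-normalization is `ln(1 + 10,000·count/total)` per cell (the
ecosystem default scale factor), preserving sparsity; the
de-logged row sum equals the scale factor to 1e-6 relative, which is
asserted as an invariant.

HVG selection uses the mean/dispersion method: dispersion =
variance/mean of de-logged values, log-dispersion z-scored within 20
equal-frequency bins of mean log expression; a gene is selected when
its standardized dispersion exceeds 0.4 and its mean lies in
(0.01, 3). The cutoffs are the published limits; note a z-score
threshold of 0.4 intentionally admits a non-trivial share of
unstructured genes — the method ranks far better than it thresholds,
and the tests assert planted-marker sensitivity (≥0.9) plus a bound on
the false-selection rate rather than a specificity the 0.4 cutoff
cannot deliver.

Gene-module scores are the mean log-normalized expression of the
module minus the mean of control genes drawn per module gene from the
same average-expression bin (25 bins, 50 controls per gene), excluding
the module itself from the control pools — without that exclusion the
score is not linear in module expression and the null is biased.
S and G2M scores use planted (or user-supplied) phase gene lists; the
phase call is S when the S score exceeds both the G2M score and zero,
G2M when the G2M score is ≥ the S score and positive, G1 otherwise.
`cc_difference` is G2M − S; the sign convention does not affect
regression.

Scaling regresses each gene's log-normalized expression on covariates
(typically n_umi, pct_mito, cc_difference) by per-gene OLS with
intercept, then z-scores the residuals and clips at ±10. Regressing
before z-scoring follows the regress-out model of the tooling era this
pipeline mirrors; collinear covariate columns are dropped with a
warning. Residual–covariate orthogonality to 1e-6·n is asserted.

## Clustering

PCA runs on the scaled HVG submatrix via SVD with a fixed sign
convention (largest-magnitude loading positive), so reruns are bitwise
identical. The scree elbow is chosen by the triangle method: the
corner is the scree point with maximal perpendicular distance to the
chord from first to last point, and the returned count keeps the
components before the corner, with near-ties broken to the smallest
index and a flat scree defaulting to 1.

The SNN graph connects cells by the Jaccard overlap of their
k-nearest-neighbour sets (k = 30, self excluded, Euclidean distance in
PC space), pruning weights ≤ 1/15. Community detection optimizes
resolution-parameterized modularity with the Leiden algorithm —
Louvain with a refinement step, the same method family as the SLM
optimizer the original analysis used; exact SLM reproduction is a
non-goal. The resolution sweep (default 0.5–6) produces a cluster
tree whose edges carry the fraction of each lower-resolution cluster
flowing to each higher-resolution cluster (out-weights sum to 1).

Markers per cluster come from a two-sided Wilcoxon rank-sum test of
the cluster against all other cells, prefiltered to genes detected in
≥25% of the cluster; log2FC compares de-logged means with pseudocount
1; Bonferroni correction is over all (gene, cluster) tests. For
instances of at most 50 cells the p-value is the exact tie-aware
permutation distribution of the rank sum (computed by dynamic
programming over the rank multiset); larger instances use the
tie-corrected normal approximation with continuity correction, which
matches scipy's asymptotic Mann-Whitney p to machine precision.

Cluster merging: a cluster's unique markers are its significant marker
genes not significant in its nearest neighbour — the cluster with the
highest centroid Pearson correlation in HVG log-normalized space (the
published procedure leaves "nearest" qualitative; centroid correlation
is our operationalization). A cluster with no unique marker is merged
into that neighbour, markers are recomputed, and the procedure
iterates to a fixed point (cap 10 iterations). It never increases the
cluster count.

## Marker-conflict doublet filter

The per-type score is `log2(1 + agg expm1 x)` over the type's panel
genes (agg = mean by default; max available), so scores are on a
common log2 scale regardless of panel size. A cell is flagged when two
types declared conflicting both score above θ = 1 — i.e. both
signatures are detectably co-expressed more than 2-fold over the
pseudocount baseline. The cutoff's reference is config-switchable:
`absolute` (default) compares the score itself to θ; `relative`
compares the score's excess over the population median for that type,
a fold-change-over-background reading.

Scope: `per-cluster` (default in the pipeline) counts only conflicts
between the cell's own cluster identity and a foreign type — the
cluster-by-cluster cleanup, where evidence of a doublet is the
cluster's own signature plus a distantly related one; `global` counts
any conflicting pair. Conflict groups are curated declarations, not
computed: related lineages share a group and are therefore exempt,
which keeps genuine intermediary states. Flagging is monotone in θ
(the flagged set at a higher θ is a subset of the flagged set at a
lower θ), independent of cell order and of genes outside the panel.
Removed cells are returned as a matrix, never silently dropped, and
`retention_check` verifies that every panel type retains at least one
high-scoring cell and that retained cells carry no conflicting signal
above θ, alongside an HVG count comparison. The HVG count is reported,
not asserted, in either direction: whether cleanup raises it is
dataset-dependent.

## CCA replicate alignment

Both data sets are restricted to a shared high-dispersion gene set
(union of each set's top-n standardized-dispersion genes, intersected
with genes detected in both) and gene-standardized. CCA is the SVD of
the cross-covariance `X1 X2ᵀ/G`, giving paired cell-space canonical
vectors with unit norm and a fixed sign convention. The canonical
correlation per CV is the Pearson correlation over genes of the two
metagenes `X1ᵀu` and `X2ᵀv`, clipped to [0,1] and reported
non-increasing; self-alignment gives CC1 = 1 exactly.

bicor follows the standard biweight midcorrelation: deviations from
the median scaled by 9×MAD, weights `(1−u²)²` inside |u|<1, falling
back to Pearson (with a warning) when a MAD is zero. It is invariant
to positive affine transforms and within 0.05 of Pearson on bivariate
Gaussian data at n = 1,000.

The saturation curve computes, per CV and data set, the bicor between
the cell projection and the data set's own metagene re-projection
`X_d(X_dᵀ proj_d)`. Using each data set's own post-hoc loadings is
essential: projecting data set 2 on data set 1's loadings is
algebraically proportional to its own projection (an identity of the
SVD), which would make the curve uninformative. A CV that reflects
real structure in a data set survives this round trip (bicor near 1);
a CV carried only by the other data set decays early. The default
floor for choosing a CV count is 0.15.

The mixing score is the mean per-cell normalized Shannon entropy of
batch composition among k = 20 nearest neighbours in the aligned
(L2-normalized) projection space: 1 = perfectly interleaved
replicates, 0 = separated.

## Trajectories

Density-peak clustering: local density ρ is a Gaussian kernel sum with
radius d_c (default: the 2% quantile of pairwise distances); δ is the
distance to the nearest higher-density cell (the global maximum takes
the largest distance). Centers are either the top-n cells by ρ·δ or,
in auto mode, cells exceeding both ρ and δ thresholds; remaining cells
inherit the label of their nearest higher-density neighbour in
decreasing-ρ order. Duplicate points are jittered with a warning.

The principal tree is the minimum spanning tree over state centroids
(Euclidean); each cell projects orthogonally onto its nearest tree
edge; pseudotime is geodesic distance from the root along the tree;
branch labels are tree segments (maximal paths between root, branch
points and leaves). This is a deliberate, documented simplification of
the iterated graph-embedding reduction used by the original tooling:
it preserves the contract downstream analysis relies on — a
root-anchored ordering with explicit branch structure — and is exactly
reproducible (the MST equals exhaustive search over spanning trees on
small instances). The root is an explicit state or the state
maximizing a root-marker module score; ties raise an error demanding
an explicit root rather than guessing. Cells near a branch point are
intrinsically ambiguous: recovery is therefore evaluated on committed
cells, and the spurious-side-branch count grows with the number of
states (8 states on ~1,500 cells is the default operating point).

Differential expression uses per-gene NB GLMs with log link on raw UMI
counts. Offsets are log median-of-ratios size factors (per cell, the
median ratio of its detected counts to per-gene means, normalized to
geometric mean 1) rather than raw library size: when a minority of
genes changes in concert, raw-library offsets make every other gene
compositionally non-null, which inflates the false-positive rate an
order of magnitude. Per-gene dispersion is estimated by Pearson-χ²
matching around the full-model Poisson fit, floored at 1e-3 —
estimating dispersion under a null or marginal model lets genuine
signal inflate it and destroys power. The pseudotime test compares a
natural cubic spline of pseudotime (df = 3) against an intercept-only
null (LRT, χ²(3)); the branch test compares branch-specific level and
spline against one shared curve (χ²(df+1)) on cells of the two
branches, and is symmetric in branch order. Genes expressed in fewer
than `min_cells` cells (5/20/50/100 are the conventional operating
points) are not tested; q-values are Benjamini–Hochberg.

A calibration caveat: the χ² reference for the NB LRT is mildly
conservative at UMI-scale counts (observed type-I error ≈ 2–3% at
nominal 5% on simulated nulls, even with the true dispersion plugged
in). Inference is therefore valid but slightly underpowered at the
margin; the tests assert type-I control, FDR ≤ 0.07 at q < 0.05, and
power at the planted effect rather than exact p-uniformity.

Gene modules cut a Ward dendrogram on 1 − Pearson distances of
z-scored fitted curves at k modules or a height. Stage boundaries
smooth each stage's marker-module score over pseudotime (Gaussian
kernel, bandwidth 5% of the range) and place each boundary at the
first grid point where the later stage's score exceeds the earlier
one's, falling back to the maximal score difference (with a warning)
when the curves never cross; intervals are contiguous, ordered and
non-overlapping.

## Shared signatures and pipeline

A shared signature between two clusters is the intersection of their
significant marker sets, ranked by mean log-normalized expression
across the two clusters, with a top-n view; an empty intersection is
an empty result, not an error. `run_pipeline` chains load → QC →
normalize → cell-cycle → HVG → scale → PCA → SNN → sweep → cluster →
markers → merge → conflict cleanup → retention → signature, writing
TSVs, a removed-barcode list and a JSON manifest with parameters,
seeds and cell accounting; stages can be skipped (recorded in the
manifest) and a rerun under the same seed is bit-identical.
Assignment of cluster identities to named cell types is a
user-supplied mapping, not automated: it rests on curated markers and
imaging evidence outside the data. Replicate alignment is a validation
stage, not a correction: the aligned projections are diagnostics, and
downstream analysis runs on the primary data set.

## The synthetic-data generator

The generator emulates the tissue the pipeline is designed for: a
handful of compact, isolated non-ovarian cell types plus one
continuous somatic lineage with a single branch point, with lognormal
library sizes centred on ~7,100 UMIs (yielding ~1,300–1,400 detected
genes of 2,000 per cell — the depth regime of the real tissue),
gamma-Poisson (NB) counts with dispersion 0.3, a pinned mitochondrial
fraction (0.4% mean, placing typical cells clearly inside the 1%
dead-cell threshold), 20% cycling cells, and 10% cross-type doublets.

Design choices worth noting:

- **Markers are near-exclusive.** A marker gene is boosted
  `2^fc` (fc = 3 by default) in its type and suppressed
  `2^(−fc·1.5)` elsewhere, giving the >100-fold in/out separation
  curated markers show in real data. A flat parameterization (boost
  only) would leave off-type marker expression around 10 per 10k —
  enough to cross the conflict filter's θ = 1 cutoff in every cell and
  make the filter's operating point meaningless. Setting fc = 0
  recovers an exact null (markers indistinguishable across types).
- **Phase programs are repressed outside their phase**, as
  replication/mitosis genes are in real cells; without repression G1
  cells score near zero with symmetric noise and the S/G2M/G1 call
  degenerates to a coin flip on half the population.
- **Branch divergence is switch-like**: 120 branch genes at 4-fold,
  activated as `sqrt` of scaled time past the branch point. A thin,
  linearly ramping program leaves a long uncommitted window in which
  branch recovery is undefined; commitment in real lineages is fast
  relative to the branch-to-terminus span.
- **Doublets** sum two cross-type parents' counts and multinomially
  downsample to a typical library, modelling droplet co-encapsulation;
  within-type doublets are excluded by construction (the filter
  targets distantly related types only, and within-type doublets are
  invisible to it by design).
- **Planted QC failures** (fragmented cells at ~300 UMIs, multiplets
  at ~45,000 UMIs, dead cells at ~10× mito content) are appended so
  threshold filtration has an exact planted answer.
- **Replicate pairs** share the gene-level model (same marker
  assignments and baselines), draw cells independently, optionally
  multiply replicate-2 gene means by `2^N(0, σ_batch)`, and can
  down-sample rarer types in replicate 2.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: ambient-RNA contamination, empirical
mean-dispersion trends (dispersion is constant across genes),
gene-gene correlation beyond the planted programs, batch effects that
are nonlinear in log space, and doublet profiles between *related*
types (which the conflict filter does not target). Performance numbers
(ARI 1.0, doublet recall 1.0) are properties of well-separated planted
types at 8-fold markers, not predictions for real tissue.

## Default problem sizes

The test-suite and the acceptance script run the default 2,000-gene ×
3,000-cell discrete simulation (five seeds for stochastic properties),
a 1,500-cell branched lineage, 900-cell replicate pairs, and 500-cell
DE cohorts with ~550 tested genes — sizes chosen so the full suite
completes in a few minutes on one CPU while keeping every planted
effect at the stated magnitude.
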