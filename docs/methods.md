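# Methods

This note documents the models, parameter choices and numerical
conventions behind each stage of atriakit, and what the synthetic-data
generators do and do not emulate.

## Droplet quality filtering

Single-nuclei preparations of cardiac tissue are contaminated by ambient
cytoplasmic RNA. A droplet that captured no nucleus still contains
cell-free transcripts, which are predominantly **spliced** (mature mRNA),
enriched for **mitochondrial** genes, and depleted of **nuclear-retained**
transcripts. The filtering model exploits exactly these axes.

**Metrics.** Per droplet: total counts; detected genes; splicing fraction
= spliced/total (0 with a warning for zero-count droplets); mitochondrial
fraction; and enrichment scores for a nuclear-localized gene set, a
cardiomyocyte marker set, and one or more non-cardiomyocyte marker sets
(plus their maximum). Scores use the binned control-gene scorer described
below, on ln(CP10K+1) data.

**Clustering.** Droplets are partitioned by k-means (default k = 4,
`n_init` = 10, seeded) after per-column standardization; zero-variance
columns are dropped with a warning and fully constant metric tables raise
a degenerate-input error. k-means is an adequate choice because the
quality space is low-dimensional and the contaminated/empty populations
form compact, convex clumps; k is configurable for tissues with more
structure.

**Cluster removal rules** (all configurable, defaults are this package's
choices): a cluster is *contaminated* when its mean mitochondrial fraction
exceeds 0.3; otherwise it is *empty* when its mean splicing fraction
exceeds 0.7 **and** its mean nuclear score lies strictly below the median
(quantile 0.5) of cluster-mean nuclear scores. The mitochondrial rule
takes precedence so that a cluster failing both is reported as
contaminated. The term "splicing fraction" here always means the
**spliced** share of counts — the quantity that is *high* in
ambient-dominated droplets; the convention is switchable by supplying
unspliced-based metrics instead.

**Per-sample outlier filter.** Within each sample, among droplets kept so
far, a droplet is dropped when its splicing or mitochondrial fraction is
strictly above median + n_mads · 1.4826 · MAD (one-sided, default
n_mads = 4). With MAD = 0 the threshold collapses to the median, so only
strictly greater values can be dropped. Samples with fewer than three kept
droplets are skipped with a warning.

Doublet detection is an external stage; `run_droplet_qc` accepts a
precomputed boolean doublet mask and records `doublet` as the removal
reason for masked droplets that survived the other filters.

## Expression pipeline

The deterministic chain is: rare-gene filter → ln(CP10K+1) → HVG →
covariate regression → scale/clip → PCA → *batch hook* → kNN → Leiden /
*embedding hook*. Batch integration and 2-D embedding are published
external algorithms (Harmony, UMAP); they are deliberately not
re-implemented and enter only through the two hook stages, which default
to identity. The hook positions fix the stage order so an integrated run
is a drop-in replacement.

Numerical conventions worth stating:

* **Normalization** uses the natural log; back-transformed row sums equal
  the target (10 000) to float precision, which the tests assert at 1e-6.
* **HVG selection** follows the classic dispersion recipe: mean and
  dispersion (variance/mean) computed on the back-transformed (expm1)
  scale, dispersions z-scored within 20 equal-frequency mean bins, cutoffs
  mean ∈ (0.0125, 3) and normalized dispersion ≥ 0.5. Equal-frequency
  binning is used (not equal-width) because it is well-defined for the
  skewed mean distributions of sparse panels; singleton bins are merged
  with a neighbour so no gene is silently dropped. Whether the cutoff mean
  is back-transformed or log-scale is genuinely ambiguous in common usage;
  the back-transformed scale is the default and `log_mean=True` switches.
* **Regression** is per-gene OLS with an always-included intercept;
  constant covariates are dropped with a warning, any further rank
  deficiency is an error. Default covariates: per-cell total counts, plus
  mitochondrial percentage when available.
* **Scaling** standardizes per gene and clips only the upper tail at 10;
  zero-variance genes become zeros.
* **PCA** is an exact SVD with a sign convention (largest-magnitude
  loading positive) so embeddings are bit-reproducible. `n_pcs` beyond the
  matrix rank is clamped with a warning.
* **kNN graph**: Euclidean, exact (blocked dense distances), ties broken
  by lower cell index via stable argsort, union-symmetrized with unit
  weights.
* **Leiden** optimizes the RBConfiguration objective (leidenalg), seeded;
  labels are relabeled to descending cluster size with ties to the lower
  original label.
* **Gene-set scoring**: genes are binned into 25 equal-frequency bins of
  mean expression; for each set gene up to 50 control genes are sampled
  (seeded, without replacement, excluding set members) from its bin; the
  score is mean(set) − mean(pooled controls) per cell. On an
  identically-distributed matrix the score is 0 by construction.
* **Marker ranking**: two-sided Wilcoxon rank-sum per gene (cluster vs
  rest), normal approximation with tie correction, exact enumeration for
  small groups (< 25 per side, when ties permit); BH correction within
  cluster; the table is ordered by (p-value, descending logFC) and
  truncated to the first 500 significant genes. logFC is the difference of
  mean log-normalized expression — a natural-log scale.
* **Doublet-cluster flagging**: a cluster is flagged when ≥ 2 reference
  types are "high", where high means the cluster-mean score is positive,
  exceeds the 0.9 quantile of pooled off-target scores (cluster/type pairs
  where the type is not that cluster's best match), and reaches at least
  0.4 of the cluster's own best score. The last ratio condition was added
  after observing that an off-target-quantile rule alone flags mild marker
  leakage in clean single-type clusters; genuine 50/50 co-expression sits
  near ratio 1, leakage well below.
* All quantiles use linear interpolation.

Subtype reprocessing is the same operation chain applied to a row subset
with an identical config object; nothing is inherited from the parent run.

For differential expression beyond marker ranking the package defines the
DE-table schema (gene, logFC, pvalue, fdr, significant) and consumes
tables produced by external mixed-model tools; "significant" defaults to
FDR < 0.05. Cluster-level disease-enrichment DE designs expose an
`enrichment_fraction` choice to the caller rather than claiming a default.

## Co-expression modules

Gene–gene correlation in single-cell data is inflated by cell–cell
structure (depth, cell state). ZCA whitening removes it: with the thin SVD
of the column-centered matrix X = U S Vᵀ, the whitened matrix is
(X Xᵀ)^(−1/2) X = U Vᵀ, whose gene-gene Gram matrix is V Vᵀ = V S⁰ Vᵀ.
Generalizing the exponent gives a resolution family: M(P) = V S^P Vᵀ,
with P = 2 the raw covariance (XᵀX) and P = 0 fully whitened. M is
normalized to correlation scale by its diagonal, C = D^(−1/2) M D^(−1/2)
(the family is only defined up to proportionality, so the diagonal
normalization is the natural gauge). Singular values below 1e-12 of the
largest are treated as numerical null space and dropped at every P
(0⁰ := 0); genes with vanishing diagonal get zero correlations and a flag.

**Sparsity-stratified z-scoring.** Sparse genes have noisier correlation
estimates. Genes are assigned to 10 equal-frequency bins of their zero
count in the **raw** count matrix (sparsity is only meaningful before
log-transformation); for each unordered bin pair the null mean and SD are
estimated from all off-diagonal entries between the two bins, and each
entry is standardized against its stratum. Stratification by bin *pair*
(rather than per-gene margins) is used because the null spread of a
correlation depends jointly on both genes' sparsity. Ties in zero counts
are broken by gene name so the binning is invariant under permutations of
the gene axis. Strata with vanishing spread score 0 with a warning.

**Graph and clustering.** Edges require z **strictly** above 4.5, with z
as weight; isolated genes remain nodes. The per-resolution graphs
(P ∈ {0, 0.5, 1}) are clustered jointly with multiplex Leiden maximizing
the equally-weighted sum of per-layer RBConfiguration quality at
resolution 2, seeded. Communities below `min_module_size` (default 2 — a
deliberately low floor, since biologically meaningful three-gene modules
exist) leave their genes unassigned; modules are ordered by size.

Whether module detection should run on all genes or an HVG subset is left
to the caller (`detect_modules` takes whatever matrix it is given); the
default examples use all genes passing the rare-gene filter.

**Annotation** is a one-sided hypergeometric upper tail on the overlap
between each module and each annotation set, both intersected with the
supplied gene universe, with BH correction across all module × set pairs.

## Hexagonal binning and spot processing

"80 px wide" hexagons are interpreted as pointy-top hexagons with
center-to-center horizontal spacing 80 px (rows 80·√3/2 apart, odd rows
offset by 40 px); the interpretation (flat-to-flat vs vertex-to-vertex vs
spacing) is a convention choice and both the width and the grid anchor
(bounding-box minimum corner) are parameters. The grid extends at least
one hexagon beyond the bounding box. Molecules are assigned by axial
(cube) rounding, verified against the six neighbouring centers, which
makes the assignment exactly the nearest-center rule with distance ties
resolved to the lowest hexagon index (row-major enumeration). Total counts
are conserved; empty hexagons are dropped.

Targeted-panel pseudo-spots (~100-gene panels) are **not** library-size
normalized — with so few genes, per-spot totals carry real signal and
normalization creates artifacts. Instead: log1p, per-gene OLS on per-spot
total counts and detected-gene counts, scaling (clip 10), PCA (top 15),
optional per-section batch hook, kNN, seeded Leiden. The Leiden resolution
for spatial data defaults to 1.0 but should be matched to the expected
domain granularity; the two-domain recovery checks use 0.1, the coarse
setting appropriate for a binary tissue partition on a ~100-spot graph.
Visium-style matrices instead follow the snRNA recipe (CP10K, log1p, HVG,
regression on totals and mitochondrial percentage, scale, PCA, kNN,
Leiden) and can be scored with snRNA-derived marker sets.

Per-gene section summaries report the normalized-log expression
distribution per section with the 1.5×IQR whisker rule; a section whose
panel lacks the gene is reported missing, never zero.

## Synthetic data: what it emulates, what it does not

**Droplets.** Three class families with distinct spliced-fraction Beta
distributions (nuclei mean ≈ 0.35, empty ≈ 0.95, contaminated ≈ 0.75),
negative-binomial depths (means 3000 / 800 / 2500), and profile weights on
a mitochondrial block (2% / 15% / 40%) and a nuclear-enriched block
(30% / 2% / 8%). The ambient profile is the abundance-weighted mixture of
the cell-type profiles reweighted toward cytoplasmic content — the
composition of real ambient RNA is not published for this tissue, so this
mixture is a stand-in chosen to reproduce the qualitative separability
that makes quality-space filtering work. Per-droplet totals are
multinomially distributed over the class profile and split
spliced/unspliced by a per-droplet Beta draw. Defaults plant 30% empty and
10% contaminated droplets among nuclei of three cardiac cell types across
4 samples. Not emulated: read-level noise, UMI collisions, barcode
swapping, doublets (an external mask stands in), or per-sample batch
effects — so passing QC tests demonstrates the geometry of the method, not
robustness to those artifacts.

**Modules.** Per module one standard-normal factor per cell; member genes
are loading·f + √(1−loading²)·ε, so two members correlate at loading²
(the closed form the tests check). Counts mode exponentiates the latent
values into Poisson rates and Bernoulli-thins to an expected zero fraction
(default 0.7), solving for the keep-probability by root finding — thinning
is in expectation, not exact, to preserve the count distribution's shape.
Real co-expression has overlapping programs, varying module strength and
mean-dependent dispersion; none of that is planted.

**Molecules.** Domains are discs or rectangles inside the slide with
categorical gene profiles; positions are uniform within the domain and
molecules are split evenly across domains. No cell morphology, optical
noise, or segmentation errors.

**DE tables.** Significant sets of controlled overlap (half the universe
significant in at least one table; the constructed Jaccard index is
returned), shared-gene logFC pairs from a bivariate normal with the
requested correlation.

All generators draw from one seeded NumPy Generator per call, so equal
configs give bit-identical output; parallel sub-streams are unnecessary at
these problem sizes.

## Problem sizes and verification

The self-checks run at desk scale, chosen so each stage is exercised with
comfortable statistical margins: 50 random 20 × 8 matrices for the ZCA
oracles (agreement to 1e-8); 5 000 cells × 200 genes with four 20-gene
modules at loading 0.8 for module recovery (ARI ≥ 0.9 across seeds, pure
noise assigns ≤ 5% of genes); 2 000 droplets per seed for QC precision and
recall (≥ 0.9); 10 000 molecules on an 800 × 800 slide for hexbin
exactness; 200 permutation replicates for Wilcoxon/BH calibration. The
`scripts/acceptance.py` entry point recomputes all of these from scratch
from a single seed.

## Known limitations

* The cluster-removal rule is a declared stand-in for unsupervised
  quality-space filtering in general; tissues where contamination is not
  separable along splicing/mitochondrial/nuclear axes need different
  metrics.
* The multiplex Leiden objective weights all resolution layers equally;
  no evidence-based layer weighting is attempted.
* Wilcoxon marker p-values are approximate under heavy ties for small
  groups; the exact path only engages when tie structure allows.
* Hexagon assignment assumes planar coordinates in a shared frame;
  no registration across sections is performed.
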