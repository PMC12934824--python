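# Methods

This note documents the statistical procedures implemented in `plaincell`,
the parameter choices behind them, what the synthetic generators do and do
not emulate, and the numerical conventions used throughout.

## Within-cell rank z-score

Each cell is normalized to itself. With fractional (average-tie) ranks
r_g over the cell's n genes, the transform is
z_g = Phi^{-1}((r_g - 0.5)/n). Conventions:

- **Percentile offset** (r - 0.5)/n keeps percentiles strictly inside
  (0, 1), so z is always finite, and places an odd-length median exactly at
  z = 0.
- **Ties** receive the mean of their rank range. This matters enormously in
  scRNA-seq, where most genes in a cell are zeros: the zero block maps to
  one shared negative value. Average ranks make the transform deterministic
  and permutation-invariant.
- **All genes participate**, including never-detected ones. The transform
  has no external reference, so there is no principled gene pre-filter at
  this stage; downstream selection handles informativeness.

Consequences verified by property tests: invariance to positive rescaling
and to any strictly increasing per-cell transform of counts (hence to
library size and monotone amplification distortions); a cell with d
distinct counts yields exactly d distinct z values.

## Projection onto a pseudo-bulk reference basis

A reference basis column is built per source label by **summing raw counts**
over the label's cells and rank-z-normalizing the summed pseudo-bulk vector.
Averaging the per-cell z rows instead is a defensible alternative; it is
exposed as `build_reference(..., method="mean_z")`, with summed-then-
normalized the default because summing counts is the standard pseudo-bulk
construction and is self-consistent with the normalization (a pseudo-bulk
"cell" normalized to itself).

With more genes than types, the columns of B span a linear subspace; the
"(non-orthogonal) projection" of a cell x is the least-squares coordinate
vector a = (B'B)^{-1}B'x, computed by a stable least-squares solve rather
than the explicit normal equations. The predicted label is the argmax
coordinate; exact ties go to the lexicographically smallest label and are
flagged. There is no score threshold or "unassigned" class. Basis
construction rejects (near-)collinear columns at a relative singular-value
floor of 1e-10, naming the most correlated label pair.

Cross-species transfer restricts both sides to a strictly one-to-one
ortholog table (rows in many-to-many relations are dropped with a count
reported) and renames target genes into the basis species' namespace. The
restriction is lossy; the retained-gene count is part of every transfer
report.

## Similarity analysis

Group profiles (per cell type or per species) are the same normalized
pseudo-bulk vectors as basis columns, but identical profiles are permitted
(their cosine is 1; a *basis* would reject them as collinear). For species
comparisons the caller restricts to orthologs and cell types shared by all
species first. The divergence analysis reports the Spearman rank
correlation (average-rank tie correction) between an anchor's cosine
similarities and user-supplied divergence times; an all-tied input is an
error rather than a silent zero, and fewer than three comparison points is
rejected as degenerate. Divergence times are user input — a documented
example at the primate scale is chimpanzee ~5 Myr and marmoset ~37.5 Myr
from human (midpoints of the commonly quoted 4–6 and 35–40 Myr ranges).

## Denoised classification

Pipeline order: rare-type filter (default min 100 cells per label) →
rank z-score → one-way ANOVA F per gene on training cells, keeping the
`n_genes` largest (default 20000; boundary ties keep the lower gene index)
→ per-gene standardization with training mean/sd (zero-variance features
are set to 0, keeping indices stable) → PCA (default 220 components,
clipped to the rank bound min(n_train - 1, n_selected) with a logged
warning) → multinomial logistic regression (L2, C = 1.0, the classifier
family conventionally used to probe representations). Standardization is
per-gene with training statistics — the only reading consistent with
leakage-free PCA; a per-cell variant would re-introduce test-time
dependence on the feature set.

Gene selection, scaling, and loadings are frozen on training cells and
applied unchanged to held-out cells; a dedicated test asserts the fitted
model is bit-identical when held-out counts are corrupted. Evaluation is
stratified five-fold cross-validation (each fold an 80-20 split), macro F1
as the headline: the unweighted mean of per-class F1 over classes present
in the truth, with F1 = 0 when precision + recall = 0. Predicted-only
classes appear in the confusion matrix but not in the mean.

## Cluster-local disease classification

The denoising front end is reused with ANOVA grouping by disease state —
the only label available before clustering; the grouping is an open design
point and is isolated in one function argument. Clustering runs on the PC
scores with no access to disease labels: a symmetric ("union") k-NN graph
(k = 15, Euclidean in PC space — the scores are already variance-scaled),
Leiden community detection, and a 20-iteration binary search on the
resolution parameter targeting ±20% of the requested cluster count
(default 15). Degenerate all-identical inputs return a single cluster with
a warning, as does a search that cannot reach the band.

Each cluster with both classes present gets its own binary logistic
classifier on the PC scores; single-class clusters (common under strong
class imbalance) get a constant predictor. Held-out cells are assigned to
the nearest train-cluster centroid (ties to the lower cluster index,
deterministically) and scored by that cluster's predictor. With
`target_clusters=1` the procedure is *exactly* the global classifier — an
equivalence the tests assert — so the local-vs-global comparison is a
controlled ablation of locality alone.

## PMI enrichment

For TF t, the high-activity set is the top decile of the TF's rank z-score
across cells (the cutoff value is included, so boundary ties all enter; a
TF with no variation is rejected). "Observing" a gene means raw count > 0.
With p_cond = k/n_high the detection rate among TF-high cells and p_marg
the marginal rate over *all* cells (TF-high cells are not excluded —
the marginal is a property of the whole dataset), the score is
PMI = log2(p_cond / p_marg), base 2 by PMI convention.

The null model is binomial sampling of k at the marginal rate:
Z = (k - n p)/sqrt(n p (1-p)) with a two-sided normal tail, replaced by the
exact two-sided binomial tail when the expected count n·p < 5. Pairs with
p_marg in {0, 1} are skipped (the statistic is undefined) and a TF is never
tested against itself. Benjamini–Hochberg correction runs jointly across
all (TF, gene) pairs; significance is q < alpha (default 0.05). Validation
against a truth table reports fold enrichment: the fraction of significant
pairs in the truth set over the fraction of all tested pairs in it.

## Geometry diagnostic

Points (for expression data: the leading 50 PC scores of the rank-z matrix,
since raw gene space is too high-dimensional for meaningful k-NN structure
at moderate cell counts) are connected in a symmetric k-NN graph — an edge
if either endpoint lists the other, which stays connected at smaller k than
the mutual variant — with Euclidean edge weights. Geodesics are all-pairs
shortest paths; the linearity statistic is the Pearson correlation between
geodesic and Euclidean distances over *connected* pairs only, with the
component count always reported so disconnection cannot silently inflate
the correlation. The Isomap embedding is classical MDS on the squared
geodesic matrix of the largest component (double-center, top eigenvectors
scaled by the square roots of their eigenvalues).

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (spec, seed).

**Multi-species atlas.** Root programs mu_{t,g} ~ N(0,1) per (type, gene)
with each type's markers (default 20) boosted by +3 on the log scale;
programs drift down a rooted tree by per-gene Brownian steps of sd
drift_scale * sqrt(branch_length). Cells draw Poisson counts at a per-cell
library (mean 2000, log-normal batch factor sd 0.3) over the softmax of
their program, followed by rate-dependent dropout P(zero) =
exp(-0.3 * expected count). Each non-root species' ortholog map retains a
random 60% of genes. Reference conditions used throughout the tests:
4 species on a unit-branch chain, 7 types, 3000 genes, 200 cells per type,
drift 0.3, retention 0.6. The similarity-recovery tests use a 6-species
chain at 800 genes, 4 types, 40 cells per type, retention 0.8 — small
enough to run in seconds while leaving the drift signal intact.

**Tissue.** Single-species variant with a shared base program, per-type
N(0, type_sd^2) deviations plus marker boosts, and two batch nuisances: a
per-cell log-normal depth factor and a per-batch power-law amplification
exponent gamma ~ LogNormal(0, batch_sd) applied to sampled counts. Both are
cell-wise monotone — the kind of distortion PCR-style amplification bias
produces — so rank normalization removes them exactly while magnitude-based
normalization does not; this is what the normalization regression guard
exercises. The first type is pinned to the range minimum (default 80 cells)
so the 100-cell filter always has something to do.

**Infection.** Well-separated transcriptional blobs; infection adds
effect_size (default 1.0) times a ±1 signature over 40 genes to the
log-program, identical / independent / sign-flipped across blobs. Two
constructions keep the "opposite" mode honest: signature genes carry a +1
baseline boost (so down-regulation is visible above the dropout floor
rather than degenerating into a one-sided detection boost), and the
infected shift is rescaled to preserve total rate within the signature
block (so infection does not steal library mass from every other gene,
which would create a globally separable direction). Default infected
fractions cycle (0.5, 0.4, 0.05) across blobs.

**TF network.** Heavy-tailed TF counts (log-normal rates, Poisson
sampling); background genes are Bernoulli-gated sparse counts with base
detection probabilities in [0.2, 0.6]. Planted targets (disjoint sets, 20
per TF) have their detection logit shifted by +2 in cells where the TF
count is in its own top decile; all other genes are independent of every
TF. At shift 0 planted and null pairs are exchangeable.

**Geometric controls.** Swiss roll (t cos t, h, t sin t) with
t in [1.5 pi, 4.5 pi], h in [0, 20], optional Gaussian noise (sd 0.05);
and a random flat of intrinsic dimension 2 (matching the swiss roll's, so
curvature is the only difference between the two controls) embedded in 50
dimensions. At higher intrinsic dimension the variance of k-NN path
detours grows and even a perfect flat's geodesic-Euclidean correlation
drifts toward ~0.95 at n ~ 10^3, which is why the matched-dimension
control is the meaningful one.

**Not emulated:** gene-length/GC bias, doublets, ambient RNA, UMI
duplication structure, negative-binomial over-dispersion (the analyses
under test are rank- and detection-based; Poisson plus dropout exercises
every code path they have), spliced/unspliced layers, and realistic
ortholog-resource ambiguity beyond random retention. Passing tests
therefore demonstrate correctness of the procedures and recoverability of
planted structure under these noise models — not performance on any real
atlas.

## Numerical conventions and edge cases

- Argmax ties in projection: lexicographically smallest label, flagged.
- ANOVA: genes with zero within-group and positive between-group variance
  get F = +inf (rank first); constant genes get F = 0; selection-boundary
  ties keep the lower index.
- Standardization: zero-variance features map to 0, never dropped.
- BH q-values: step-up with clipping at 1, stable under p-value order.
- Geodesic correlations: connected upper-triangle pairs only; fewer than 3
  pairs reports NaN rather than a fabricated value.
- All randomness flows through explicit integer seeds; refits and re-
  simulations are bit-identical.

## Known limitations

- The projection scores are not calibrated probabilities; margins are
  reported but have no probabilistic interpretation.
- The resolution search targets a cluster-count band, not an optimum of
  any clustering objective; two nearby seeds can land on different counts
  within the band.
- The PMI null treats detections as independent Bernoulli draws at the
  marginal rate; correlated detection (e.g., via library-size variation)
  inflates |Z| slightly, which the FDR calibration tests bound but do not
  eliminate.
- Isomap embeddings of disconnected graphs cover only the largest
  component; excluded points carry NaN coordinates.
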