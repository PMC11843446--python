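# Methods

## Model and testing cascade

Each feature is modelled by five nested linear models combining an
intercept, L continuous nutrition covariates W, K−1 treatment dummies
(control as reference) and their products. Predictor matrices are built
once per design; exactly collinear columns are removed by greedy
left-to-right rank selection (Gram–Schmidt with one re-orthogonalization
pass, relative tolerance 1e-8). Left-to-right selection guarantees that
the kept column set of a submodel is a subset of every model that extends
it, so extra-sum-of-squares degrees of freedom stay consistent even when
the nutrition variables are exactly dependent (in feeding data the
macronutrient energies sum to total energy). Fits use a QR basis of the
kept columns; residual df = n − rank.

**Global layer.** The screen for "any experimental effect" is a
permutation F test of the intercept-only model against the full
interaction model. The observed statistic is the usual extra-sum-of-squares
F; the null distribution re-assigns the observed abundance values to
samples uniformly at random, B times, with the design fixed, and
p = (1 + #{F_perm ≥ F_obs})/(B + 1). Two implementation choices matter:

* *Value-multiset permutation.* Permutations are applied to the sorted
  abundance values against a canonically ordered design (samples ordered
  lexicographically by their design row and abundance). The permutation
  draws are then a function of the data multiset only, making p-values
  exactly invariant under any joint reordering of (W, D, z) — a property
  we assert in tests.
* *Per-feature counter-based seeding.* The generator for feature j is
  seeded by (master seed, j), so p-values for a feature do not depend on
  how many other features are present or processed — adding features to a
  matrix leaves earlier features' p-values bit-identical.

Zero-variance features get p = 1 by convention. If n is too small to fit
the interaction model the feature is flagged untestable and assigned
"nonsig" with a warning.

**Interaction and main-effect layers.** Parametric extra-sum-of-squares F
tests (M2 vs M1; then M4 vs M2 for treatment and M3 vs M2 for nutrition
on the remainder). A feature with both or neither main effect significant
falls in the additive group "N+D", mirroring the set-difference
definition of that group. The treatment-only group is "D" (α ≠ 0, β = 0)
and the nutrition-only group is "N" (β ≠ 0, α = 0), i.e. labels follow
the semantic definition of the hypotheses, not the model numbering.

**Multiplicity.** Hierarchical adjustment: within each layer, Bonferroni
over the number of features actually tested at that layer; a feature
enters a layer only if its parent hypothesis was rejected. Bonferroni is
the default because it is the named procedure in the protocol we follow;
it controls FWER, not FDR, and a Benjamini–Hochberg switch
(`adjust_method: bh`) is provided for the common case where B cannot be
made large. With Bonferroni the permutation-p floor 1/(B+1) must fall
below α/p to allow any rejection; the classifier warns when it cannot and
the rule B ≥ p/α sizes the permutation count a priori. A rank-transform
flag (`rank_transform`) runs the cascade on per-feature ranks for heavy-
tailed data.

## Consensus clustering

Distances: 1 − Pearson, 1 − Spearman, and Euclidean on per-feature
z-scores (the canonical menu for abundance profiles; zero-variance
features are put at distance 1 from everything under the correlation
metrics). Base methods and their data-driven defaults:

* affinity propagation — precomputed similarity (negative distance;
  negative *squared* distance for the Euclidean metric, matching the
  method's own convention), preference = median similarity, damping 0.9
  (correlation-scale similarities do not converge at the default 0.5);
* Louvain on a kNN graph — k = ⌈√p_g⌉, edge weight exp(−d/median d);
* average-linkage hierarchical clustering with an adaptive gap cut: the
  dendrogram is cut inside the widest gap between consecutive merge
  heights among the last ⌈s·m⌉ merges (sensitivity s, default 0.5, plays
  the role of a deep-split knob); a gap under 5% of the height range
  means no structure and one cluster. This is an in-house tree-cut
  variant exposing a single sensitivity parameter;
* DBSCAN — precomputed distances, min_samples 5, eps at the knee (largest
  jump) of the sorted 5-NN distance curve; noise points become singletons
  in co-membership.

Every (method × metric) labelling contributes a binary co-membership
matrix; their element-wise mean is the consensus matrix. Edges with
consensus weight > 0.5 ("a majority of runs agree") form a weighted graph
clustered by seeded Louvain (resolution 1.0); isolated features become
singletons. A failing base method is logged and skipped; if all fail the
group is kept whole. Groups below `min_group_size_for_clustering`
(default 10) are not subclustered. Subclusters are renumbered by
decreasing size with ties broken by smallest member index.

## Interpretable statistics and annotation

* Set 1: √(n−3)·atanh(cor(z_j, w_l)) — unit variance under the null, so
  a standard-normal threshold applies. The variant that *divides* by
  √(n−3) is kept behind `literal_set1_scale` for comparability, but its
  null variance shrinks with n and it will essentially never cross the
  threshold; we treat the scaling as a typographical variant.
* Set 2: Welch t of each treatment group against control.
* Set 3: (atanh r_k − atanh r_1)/√(1/(n_k−3) + 1/(n_1−3)) — the classical
  two-independent-sample comparison of correlations, which standardizes
  the treatment-vs-control shift in the nutrition association and is the
  interaction signature used for annotation. Cells with a group of ≤ 3
  samples or a zero-variance input are missing.

Ternarization threshold: the standard-normal quantile at
`ternarize_quantile` (default 0.95 → 1.6449). An annotation record is
emitted when the fraction of members at +1 (or −1) strictly exceeds
`proportion_threshold` (default 0.7); missing member statistics count in
the denominator but never the numerator, so sparse cells annotate
conservatively. |r| = 1 is clamped to atanh ±38 with a warning.

## Over-representation

One-sided hypergeometric tail P[X ≥ overlap] per gene set, universe = all
features retained in the omics matrix after QC (standard competitive ORA
practice), sets intersected with the universe first, BH across the sets
tested for a subcluster (this layer describes rather than gates, so FDR
is appropriate; Bonferroni is a switch).

## Network

Feature–phenotype Spearman ρ with t-approximation p-values; entries with
p ≥ .01 are set to zero. The protocol sentence we implement reads
literally as zeroing the *significant* entries; we invert it — zeroing
the non-significant ones — as the only reading consistent with building a
network from significant links. This inversion is deliberate and worth
flagging to anyone comparing implementations.

Subcluster–phenotype edges use a competitive two-sided Wilcoxon rank-sum
test comparing members' |ρ| against all non-members (a mean-rank normal
approximation is available via `multiset_method: meanrank`); edge if
p < .01, sign = sign of the Spearman correlation between the per-sample
median profile of the subcluster and the phenotype. Hub features are the
top 5 members by |Pearson correlation| with the subcluster's PC1 (SVD of
the centred/scaled member matrix, PC1 oriented to correlate non-negatively
with the mean member profile so hub selection is reproducible; ties break
by feature ID).

## Synthetic data

The generator emulates a geometric-framework feeding trial: five
protein:carbohydrate:fat ratios × two energy densities (8 and 13 kJ/g)
give 10 diets; each diet × treatment cell (control + 3 drugs) holds
`n_per_cell` animals (default 2, n = 80). Grams eaten follow compensatory
feeding (inverse to density) with 10% CV lognormal-like noise; the four
intake columns are food grams and the three macronutrient energies, which
sum exactly to grams × density — so W is strongly dependent by
construction, as in real intake data. Features are drawn from their model
class with coefficients on the *standardized* W (effect scales are per
noise-sd: defaults β = 1, α = 2, γ = 1, noise sd 1); features sharing a
pattern share coefficient sign vectors with ±20% magnitude jitter, which
plants recoverable subcluster structure. Linked phenotypes equal
strength × the standardized mean profile of a pattern plus unit noise.

What the generator does **not** emulate: missing-at-random or
intensity-dependent proteomics missingness, batch structure, non-Gaussian
(e.g. compositional count) noise beyond the rank-transform option, and
correlated residuals between features within a pattern beyond the shared
mean structure. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated factorial conditions, not
robustness to those real-data complications.

## Problem sizes used in the automated checks

Null error control uses 100 replicates of 200 null features (n = 80,
B = 500); class recovery 5–10 replicates of 250 features (50 per class,
B = 5999, sized by the B ≥ p/α rule); clustering recovery 10–20 seeds of
150 features in 3 patterns at 5-sd separation; network recovery 20 seeds
of two 20-feature subclusters with link strength 3. These sizes give
stable Monte-Carlo estimates while keeping the whole suite fast on one
core.

## Known limitations

* The global permutation test is exchangeable-null based; heteroscedastic
  noise across treatment groups is not specifically accommodated.
* Bonferroni with permutation p-values requires B to grow linearly with
  the feature count; for very large matrices use `adjust_method: bh`.
* The nonlinear (smooth-term) variant of the nested-model family and
  compositional-microbiome test plug-ins are out of scope.
* The adaptive gap tree cut is a simple variant; dendrograms with nested
  structure at several scales may merge sub-patterns that a full dynamic
  tree cut would separate.
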