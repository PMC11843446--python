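# enodal

Experiment-guided clustering and annotation of high-dimensional omics
features measured under a factorial design that crosses **continuous
nutrition variables** (e.g. food, protein, carbohydrate and fat intake)
with a **categorical treatment** (e.g. control plus several drugs). The
motivating setting is geometric-framework feeding studies in mice, where
thousands of liver proteins respond to diet, drug, or both — but the
method applies to any features-×-samples matrix collected under such a
design (proteomics, metabolomics, microbiome, transcriptomics).

Unsupervised clustering of such data can confound real treatment-dependent
responses with the study design: two features that respond *oppositely* to
nutrition under different drugs can still be marginally correlated and end
up in the same cluster. `enodal` instead lets the experiment guide the
clustering.

## Method

For feature *j* with abundance *z*, nutrition row vector *w* (L columns)
and treatment level *k* (control *k* = 1), five nested linear models are
fitted per feature:

```
M1: z = μ + wβ + α_k + wγ_k + ε      (interaction)
M2: z = μ + wβ + α_k + ε             (additive)
M3: z = μ + α_k + ε                  (treatment only)
M4: z = μ + wβ + ε                   (nutrition only)
M5: z = μ + ε                        (no effect)
```

**Stage 1 — testing cascade.** A permutation F test of M5 against M1
(abundances permuted across samples, design fixed) screens for any
experimental effect; survivors are tested for interaction (M2 vs M1,
label `NxD`), then for treatment (M4 vs M2) and nutrition (M3 vs M2)
main effects (`D` = treatment only, `N` = nutrition only, the rest
`N+D`). P-values are Bonferroni-adjusted within each layer over the
features actually tested there (Benjamini–Hochberg available).

**Stage 2 — consensus clustering.** Each group is subclustered by an
ensemble (affinity propagation, Louvain on a kNN graph, average-linkage
hierarchical clustering with an adaptive tree cut, DBSCAN) across three
distance metrics; binary co-membership matrices are averaged into a
consensus matrix and the thresholded consensus graph is clustered by
Louvain. Subclusters are named `N_C1`, `NxD_C2`, … by decreasing size.

**Stage 3 — annotation.** Per feature: √(n−3)·atanh r Fisher z against
each nutrition variable (Set 1), Welch t of each treatment vs control
(Set 2), and a two-sample Fisher-z correlation shift per (nutrition,
treatment) cell (Set 3). Statistics are ternarized at the ±95% normal
quantile; a subcluster is annotated whenever strictly more than 70% of
members agree in direction. Subclusters are also tested for gene-set
over-representation (hypergeometric, BH) against a user GMT file.

**Stage 4 — network.** Feature–phenotype Spearman correlations screened
at p < .01; subcluster–phenotype edges from a competitive rank test on
the members' |ρ| (sign = Spearman of the subcluster median profile vs
the phenotype); each subcluster contributes its top-5 hub features by
|correlation| with its first principal component.

## Worked example

Simulate a study-shaped dataset (10 diets × 4 treatments × 2 replicates,
n = 80; 50 features planted per model class) and run the full pipeline:

```bash
enodal simulate --out sim --seed 2
printf 'n_permutations: 5999\nseed: 2\n' > cfg.yaml
enodal run --design sim/design.tsv --omics sim/omics.tsv \
           --phenotypes sim/phenotypes.tsv --config cfg.yaml --out out
```

`out/assignments.tsv` then classifies every planted feature correctly:

```
label
NxD       50
N+D       50
D         50
N         50
nonsig    50
```

Stage 2 recovers the two planted response patterns inside every group
(e.g. `NxD_C1`/`NxD_C2` with 25 features each), and `out/annotations.tsv`
describes them, e.g. for `NxD_C1`:

```
negatively correlated with intake_g                                 1.00
up-regulated under drug1                                            0.92
decreased correlation with protein_kj in treatment group drug1      1.00
```

(the number is the fraction of members agreeing in direction). The
network stage links the simulated phenotype, which was generated from the
first interaction pattern, most strongly to that subcluster:

```
source       target  edge_type             sign  p
pheno_M1_P1  NxD_C1  subcluster-phenotype  +     3.4e-17
```

Note on permutation counts: with Bonferroni adjustment across p features
the smallest achievable permutation p-value 1/(B+1) must fall below
α/p, so choose B ≥ p/α (the tool warns when it cannot).

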