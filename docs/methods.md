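# Methods

## Descriptor model

A peptide of length L is mapped to a star-graph recurrence network with
L + 1 nodes: a virtual center plus one node per sequence position.  Every
distinct residue letter owns one branch; the first occurrence of a letter
attaches to the center and each later occurrence chains to the previous
occurrence of the same letter, in sequence order.  The graph is therefore
connected, loop-free and has exactly one branch per residue type.  An
optional *embedded* variant superimposes the linear backbone by also
joining consecutive positions; the non-embedded graph is the default, and
nothing downstream depends on which variant is chosen as long as it is
used consistently (the CLI exposes `--embedded` everywhere).

The Markov matrix is the degree-normalized adjacency, Π = D⁻¹A, which is
row-stochastic by construction (star graphs have no isolated nodes).  The
initial distribution p₀ is uniform over *all* nodes, center included: the
center is an ordinary graph node, and excluding it from either the walk
or the entropy sum would be an arbitrary asymmetry.  The descriptors are
the Shannon entropies of p₀Πᵏ for k = 0…5, in nats (the logarithm base
only rescales features, and per-fold standardization removes scale
anyway).  θ₀ = ln(L + 1) depends on p₀ alone; only θ₀ and θ₅ feed the
final feature set, but the full series is emitted because it costs
nothing and is useful diagnostically.  Entropies always lie in
[0, ln(L + 1)] and are invariant under any relabeling of the residue
alphabet, since relabeling induces a graph isomorphism.

Nonstandard residue letters (B, J, O, U, X, Z) are accepted and form
branches of their own: curated epitope sequences contain them, and
rejecting them would silently shrink real datasets.

## Perturbation features

A record pairs a query and a reference peptide under five categorical
condition factors (organism, host, process, technique, adjuvant); the
sixth, implicit factor Seq is the set of all records.  The perturbation
of a descriptor under a factor is its deviation from the arithmetic mean
descriptor of all records sharing that record's category (the grand mean
for Seq) — the moving-average construction standard in perturbation-
theory QSAR.  Means are computed from the *query* descriptors and reused
for the reference perturbation of the same record, which keeps one
consistent expectation per category.  A consequence worth stating: since
query and reference share the record's category, the category mean
cancels in every difference feature, so Δθ_k(c_j) = ᵠθ_k − ʳθ_k for each
factor and the six Δ columns with a common k are numerically redundant in
this single-condition-set formulation.  They are kept because the
ten-column contract is the model's interface, and tree ensembles are
indifferent to duplicated columns.

Two scopes for the means are provided.  *Reproduction* mode (default)
fits them on the full table — matching how a single precomputed feature
table must be built.  The *leakage-safe* mode refits them on training
folds only and assembles both splits from those means; a category unseen
in training either raises (default) or falls back to the grand mean.
The CLI's `--leakage-safe` flag writes one train/test table pair per
fold, since fold-dependent features cannot live in one static file.

Deduplication collapses rows identical in all ten features and the label
after serializing features at six decimal places — robust to float noise,
reproducible across platforms, and idempotent; row order is preserved so
"keep first" is well defined.

## Evaluation protocol

Stratified five-fold cross-validation (class ratio preserved to within
one instance per fold), shuffled with a single top-level seed that also
drives every stochastic learner.  Standardization is fitted on the
training split of each fold only.  Class weights are inverse-frequency
(w_c = N / 2n_c, or the proportional w₀ = 1 normalization — the two are
equivalent for every learner here) computed on the training labels and
passed to all weight-aware methods; k-nearest neighbors has no weighting
and this is logged rather than silently ignored; XGBoost receives the
ratio w₁/w₀ as its positive-class weight.  AUROC is computed by the
Mann–Whitney rank statistic with half-credit for ties.  The seven methods
run at toolkit defaults except KNN k = 5 and the random-forest tree count
(10 for the method comparison; the scan covers
5, 10, 20, 30, 40, 50, 100, 200, 500, 1000 on identical folds so that
per-fold differences are paired).  Feature importances are per-fold
impurity importances of a 100-tree forest, averaged across folds.

## Synthetic data

The generator emulates curated epitope assay tables at desk scale:
peptides of 5–30 residues over the 20 standard amino acids drawn from a
reused pool (one distinct sequence per ~20 records, mirroring how real
assay tables reuse sequences); factor vocabularies of 50/20/15/28/30
categories with Zipf-skewed frequencies (exponent 1.1 — condition
frequencies in curated data are heavy-tailed, and uniform categories
would make perturbations unrealistically homogeneous); a 1.84 : 1
intermediate-to-high class imbalance.  Labels are drawn from a logistic
model on the z-scored features computed by the *actual* descriptor and
feature code, so end-to-end tests exercise the code users run.  The
default truth combines moderate linear effects (ε_r: 0.8, Δθ₅(Seq): 0.6)
with a dominant interaction (weight 3.5 on the product of two z-scored
difference features), planting non-linearity that separates tree
ensembles from linear models; labels are then flipped at a 2% noise
rate.  The intercept is solved numerically so the post-noise expected
positive rate hits the imbalance target.  Two auxiliary presets serve
specific checks: a noise-free, interaction-free strong linear truth (the
separable limit, where linear and forest models agree) and a truth
concentrated on ε_r (importance-recovery checks).

What the generator does *not* emulate: biologically realistic sequence
motifs, the true joint distribution of organisms and hosts, multiple
assay condition sets per reference peptide, or label structure beyond the
binary split.  Passing tests therefore demonstrate correctness of the
pipeline's algebra and protocol and qualitative orderings (non-linear
over linear, importance recovery), not quantitative performance on real
epitope data.

## Problem sizes and numerics

The interaction-gap and tree-scan checks run at 20,000 records, the
seven-method comparison and importance-recovery checks at 4,000 — sizes
chosen so kernel SVMs remain cheap while binomial noise on fold AUROCs
(≈0.01) is far below the effects asserted (≥0.05 gap).  Category means
use float64 pairwise summation; per-category perturbation sums vanish to
<1e-9 at these sizes.  Difference-feature antisymmetry under
query/reference swap is exact in IEEE arithmetic because the swap
reverses a single subtraction.  Degenerate inputs fail loudly: empty or
non-letter sequences, single-class label vectors, classes smaller than
the fold count, non-finite features, and unreachable imbalance/noise
combinations all raise with the offending item named.

## Known limitations

The exact settings of the original descriptor software lineage
(embedded vs. non-embedded graphs, the initial distribution, any length
normalization of entropies) are not fully documented; both graph
variants are exposed and the uniform p₀ is a stated choice rather than a
verified one.  Published full-scale results were computed on a deposited
~709k-row feature table; this package ingests such tables (alias-mapped
column names) but does not ship or fetch them, so full-scale values are
reproducible only by users holding the deposit.  With one condition set
per record the Δ features are redundant across factors, as noted above;
modeling distinct query and reference assay conditions would remove the
redundancy but requires pair metadata this formulation does not carry.
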