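# epitope-ptqsar

Perturbation-theory QSAR modeling of linear B-cell epitope activity from
peptide sequences and experimental-condition context.

## The problem

Predicting whether a candidate peptide will behave as a *positive-high*
B-cell epitope (versus merely positive-intermediate) normally requires a
wet-lab assay.  Curated immune-epitope data, however, records huge numbers
of assays of *reference* epitopes of known activity, each under specific
experimental conditions: the epitope's source organism, the host organism,
the in-vivo process, the experimental technique, and any adjuvant
additive.  This package implements a pairwise QSAR formulation: the
activity class ε_q of a *query* peptide is predicted from the known class
ε_r of a reference peptide plus descriptors of how both sequences deviate
from what is typical under the shared assay conditions.

## The model

**Descriptors.** Each peptide sequence is embedded as a star-graph
recurrence network: one branch per residue type radiates from a virtual
center node, with repeated residues chained along their branch in order
of occurrence.  Degree-normalizing the adjacency matrix gives a
row-stochastic Markov matrix Π.  Starting from the uniform distribution
p₀ over all nodes, the descriptors are the Shannon entropies (in nats)

θ_k = −Σᵢ pᵢ(k) ln pᵢ(k),  p(k) = p₀ Πᵏ,  k = 0…5.

**Perturbation features.** For a condition factor c_j (Seq, Org, Host,
Proc, Tech, Adju), the perturbation of θ_k is its deviation from the mean
descriptor of all records sharing the record's category of c_j (for Seq,
the grand mean).  Difference features Δθ_k(c_j) subtract the reference
perturbation from the query perturbation under the identical category.
The model's ten inputs, in order:

ε_r, ᵠθ₅(Seq), ᵠθ₀(Org), ᵠθ₀(Tech), Δθ₅(Seq), Δθ₀(Host), Δθ₀(Adju),
Δθ₀(Proc), Δθ₀(Org), Δθ₀(Tech)

**Evaluation.** Seven classifiers — KNN (k = 5), linear- and RBF-kernel
SVM, logistic regression, decision tree, random forest, XGBoost — are
compared under stratified five-fold cross-validation with per-fold
standardization and inverse-frequency class weights, scored by AUROC (the
probability that a random positive outscores a random negative; the right
metric for the ~1.84 : 1 class imbalance).  A random-forest tree-count
scan on identical folds and a fold-averaged impurity feature-importance
ranking complete the protocol.

A synthetic-data module generates assay-like pair tables (Zipf-skewed
condition categories, realistic imbalance) whose labels are drawn from a
known logistic truth — including a planted feature interaction no linear
model can represent — *through the real descriptor pipeline*, so every
stage is testable end to end.

## Worked example

```
epitope-ptqsar synth --n 10000 --seed 7 --out pairs.csv --truth truth.json
epitope-ptqsar features --in pairs.csv --out features.csv --no-dedup
epitope-ptqsar benchmark --in features.csv --out results/ --methods lr,rf --seed 42
```

prints (tail of the run):

```
wrote 10000 records to pairs.csv (positive rate 0.358)
wrote 10000 feature rows to features.csv
LR           AUROC 0.670 +/- 0.0044
RF           AUROC 0.887 +/- 0.0057
wrote results/auroc_by_fold.csv and results/auroc_boxplot.png
```

The generator's default truth puts most of its signal into a product of
two difference features, so logistic regression is capped near the AUROC
reachable from the linear part (the reference class and the sequence-level
entropy difference) while the random forest also captures the interaction
— the ordering the pairwise perturbation formulation is designed to
expose.  `epitope-ptqsar rfscan` scans forest sizes on identical folds and
`epitope-ptqsar importance` ranks the ten features; with the default
truth, the reference activity ε_r dominates the ranking.

Descriptors alone, from FASTA:

```
epitope-ptqsar descriptors --in peptides.fasta --out theta.csv
```

Users holding a precomputed pair-feature table (e.g. a published deposit)
can ingest it directly — column names are alias-mapped case-insensitively
onto the canonical order — and run the same `benchmark` / `rfscan` /
`importance` commands on it.

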