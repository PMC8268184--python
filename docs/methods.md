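# Methods

## Problem setting

Given an annotated cells × genes expression matrix and a weighted gene–gene
interaction network, learn a classifier that assigns cell-type labels (with
calibrated probabilities and an optional "unassigned" outcome) to new cells.
The premise is that expression is shaped by gene interactions: a convolution
over the interaction graph can aggregate weak, correlated signal across a
gene's neighborhood that a dense layer treats as independent coordinates.

## Gene graph

The graph is built over the N selected genes only, in the variance-ranked
order produced by preprocessing (that order is the single source of truth;
graph, model, and checkpoints all assert it).

* **Interaction source.** A STRING-style table (`protein1 protein2
  combined_score`, whitespace- or tab-delimited, optional protein→gene ID
  mapping). Repeated or reversed pairs keep the maximum score — STRING
  exports list each pair once per direction; self-pairs are dropped.
* **Cosine source.** Pairwise cosine similarity of gene expression profiles
  across cells, keeping pairs with similarity ≥ 0.6 (configurable); a
  zero-norm profile gets no edges.

Raw weights W are row-normalized (A′_ij = W_ij / Σ_j W_ij, zero rows stay
zero) and then symmetrized as (A′ + A′ᵀ)/2. Row normalization alone destroys
symmetry, and the spectral factorization below needs a symmetric matrix;
averaging with the transpose is the smallest change that restores it. Cosine
weights are pushed through the same normalization so both sources share one
downstream code path.

Selected genes with no surviving edges ("singletons") are kept as isolated
nodes. With the 0/0 → 0 convention for degree-zero rows, a singleton's
Laplacian row is an identity row, so its expression passes through every
Chebyshev filter unchanged — the filter cannot invent neighbors, but it also
does not silence isolated genes.

## Spectral convolution

L = I − D^(−1/2) A D^(−1/2) is symmetric positive semidefinite with
eigenvalues in [0, 2]. It is rescaled to L̃ = 2L/λ_max − I so its spectrum
lies in [−1, 1], the natural domain of Chebyshev polynomials. λ_max is
computed by an iterative sparse eigensolver (tolerance 1e−6) by default; an
`approx2` mode substitutes the analytic bound λ_max ≤ 2, which only rescales
the learned coefficients. If the eigensolver fails to converge the code
falls back to the bound with a warning.

A spectral filter h(Λ) applied to a signal x would require the dense
eigendecomposition x*h = U h(Λ) Uᵀ x. Truncating h to a degree-(K−1)
Chebyshev expansion turns this into K sparse matrix–vector products via the
recursion T_k(L̃)x = 2L̃ T_{k−1}(L̃)x − T_{k−2}(L̃)x, with T_0 = I and
T_1 = L̃ — no eigendecomposition, and the filtered value at a gene depends
only on its ≤ (K−1)-hop neighborhood. The test suite checks the recursion
against the dense spectral route to 1e−8 on random graphs, plus permutation
equivariance, linearity, and singleton locality.

## Network architecture

Defaults (all configurable through `ModelConfig`):

| parameter | default | meaning |
|---|---|---|
| N | 1000 | genes kept (top variance) |
| K | 5 | Chebyshev order = receptive field |
| F | 5 | convolution filters |
| p | 8 | max-pool block (genes per pooled node) |
| GCN embed | 32 | θ₁ size |
| NN hidden | 256, 32 | θ₂ branch widths |
| λ₁, λ₂, λ₃ | 1, 1, 1e−4 | loss weights (classification, reconstruction, L2) |
| batch, epochs | 64, 50 | SGD schedule |
| lr, momentum | 0.01, 0.9 | SGD hyperparameters |
| reject threshold | 0.65 (opt-in) | unassigned cutoff |

Each filter owns an independent K-vector of coefficients β_f over one shared
Chebyshev basis, plus a scalar bias before the ReLU (the bias is a config
flag, default on). Pooling takes contiguous blocks of p genes in the
variance-ranked node order with a zero-padded tail — deterministic and
order-canonical; graph-aware coarsening is out of scope. The pooled map
(⌈N/p⌉ × F, 625 values at defaults) is flattened and projected to θ₁ ∈ ℝ³².
A linear decoder maps θ₁ back to ℝᴺ; it reconstructs the normalized input
(the network's actual input), the only self-consistent choice. The NN
branch is N → 256 → 32, ReLU throughout. The output layer reads
θ₃ = [θ₁, θ₂] ∈ ℝ⁶⁴ (GCN features first) and softmaxes over the n types.

The closed-form parameter count
F·K [+ F] + (⌈N/p⌉·F·32 + 32) + (32·N + N) + (N·256 + 256) + (256·32 + 32)
+ (64·n + n) is asserted against the instantiated model for several
configurations.

### Loss and optimization

* classification: mean over the batch of −log p_y, probabilities clipped at
  1e−12 so an exactly-zero probability stays finite;
* reconstruction: per-cell **sum** of squared errors over genes, then mean
  over the batch — keeping the within-cell sum preserves the intended
  λ₂ : λ₁ balance (reconstruction error scales with N), while the batch
  mean keeps both terms independent of batch size;
* regularization: Σ w² over **all** trainable parameters, including biases
  and Chebyshev coefficients.

Glorot-uniform initialization and per-epoch shuffling are seeded; SGD uses
classical momentum. There is no early stopping or schedule: the model trains
a fixed 50 epochs and validation metrics are recorded for monitoring only.
Two runs with the same seed and thread count are bitwise identical — the
implementation is plain numpy, so no GPU/cuDNN nondeterminism exists.
Because the expression input is a leaf of the computation graph, no gradient
flows through the Laplacian products; backpropagation touches the Chebyshev
stack only through the β coefficients, which keeps the hand-written backward
pass small. It is validated against central finite differences (1e−4
relative tolerance; absolute differences under 1e−8 are treated as
agreement since they sit below the central-difference roundoff floor for
this loss).

### Rejection

`predict` flags a cell unassigned when its top probability is below the
threshold, but retains the argmax label alongside the flag, so reports can
be computed both including rejections (they count as errors and as false
negatives for the true class, never as false positives) and excluding them
(with the rejection rate reported separately).

## Preprocessing

Fixed order, enforced: filter cells (unlabeled/debris/doublet,
case-insensitive) → filter all-zero genes → log2(x+1) → per-gene min–max →
top-N variance selection → stratified 80/10/10 split. Decisions where the
procedure left room:

* log base 2 — scRNA-seq convention; the base rescales variances uniformly
  and cannot change their ranking;
* min–max per gene across cells — per-gene scaling is what makes the
  subsequent variance ranking meaningful; constant genes map to 0 rather
  than NaN;
* variance computed after the log/min–max transform, matching the pipeline
  order;
* normalization uses whole-dataset statistics before splitting. This
  matches the intended usage but leaks test-set minima/maxima into
  training; documented rather than hidden;
* the split is stratified per class (remainder to train, at least one cell
  in validation and test for classes of ≥ 3 members; smaller classes are
  confined to train with a warning) — unstratified splits can leave empty
  test classes, which breaks median-F1;
* variance ties break lexicographically by gene ID for reproducibility;
* a `normalized` flag travels with the matrix and `log_and_minmax` refuses
  to run twice — min–max is not idempotent and silent re-scaling is a
  classic pipeline bug.

For cross-dataset work, each dataset is normalized independently, restricted
to the shared cell types, inner-joined on genes, and stacked with per-cell
provenance for leave-one-dataset-out evaluation. A centroid-distance density
(per-class mean profiles, pairwise Euclidean distances, Gaussian KDE with
Scott's rule) summarizes how separable a dataset's populations are.

## Evaluation

Accuracy, per-class one-vs-rest precision/recall/F1 with the 0/0 → 0
convention (keeps medians defined when a class is never predicted), their
medians across classes, labeled confusion matrices, and one-vs-rest ROC/AUC
per class. ROC points and the trapezoidal AUC are delegated to
scikit-learn's `roc_curve`/`auc` (tied scores move between confusion cells
together); tests cross-check the AUC against a pairwise Mann–Whitney count.
Classes without positives or negatives report NaN AUC with a warning.
Statistical comparison of correlated AUCs between classifiers is out of
scope; raw curves are returned so users can run such tests elsewhere.

## Synthetic data generator

The generator exists so the full pipeline — graph construction, spectral
filtering, training, rejection, evaluation, CLI round trips — is exercisable
with no external downloads. It emulates the qualitative regime of annotated
scRNA-seq references: class-labeled cells, class signal partly localized on
a known gene graph, overdispersed counts, and zero inflation.

Defaults: 200 genes, 1000 cells, 4 balanced classes; 10 graph modules of 15
genes with within-module edge probability 0.6 and uniform weights in
[0.4, 1.0]; ≥ 25% of genes reserved as singletons; each class elevates 2
modules (disjoint across classes when enough modules exist) plus 5 off-graph
genes by 2^1.5 ≈ 2.8-fold over a base mean of 5; counts are gamma–Poisson
(negative binomial, dispersion 0.3, variance μ + 0.3μ²) with 30% Bernoulli
dropout. Module sizes and rates were chosen once as a plausible desk-scale
caricature of droplet data — strong enough that a competent classifier
clears 90% test accuracy, noisy enough that it cannot memorize.

What it does **not** emulate: library-size variation, batch effects,
ambient RNA, doublets, gene-length bias, realistic gene–gene correlation
beyond the planted modules, or any specific published dataset. Passing tests
demonstrate that the implementation recovers planted structure under
NB-plus-dropout noise, not that it matches any particular atlas's accuracy.

With `global_signal_genes_per_class = 0` all discriminative signal lies on
graph modules; that is the regime where the graph branch is expected to
matter, and it is where the full-model vs NN-only ablation is compared
(medians over 3 seeds tie or favor the full model there; under the default
generator the 20 extra off-graph marker genes reward the plain NN branch
and the comparison is uninformative about the graph).

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` run at desk scale, chosen so the
full verification stays interactive: spectral checks on graphs of ≤ 50
nodes, gradient checks on a 16-gene toy network, training runs on the
default 1000 × 200 synthetic fixture (50 epochs, a few seconds each on one
CPU), metric oracles on 500 random predictions. Larger inputs only change
runtime, not any code path.

## Known limitations

* No GPU path and no minibatch parallelism; desk-scale N = 1000 is the
  design point, and very large atlases (10⁵+ cells) will train slowly.
* λ_max, the graph, and the gene order are frozen at training time; a
  checkpoint refuses prediction against a mismatched gene order rather than
  attempting to remap.
* The rejection rule thresholds the raw softmax maximum; probabilities are
  not calibrated, so the threshold's meaning drifts with class count.
* Whole-dataset normalization before splitting (see above).
* The cosine graph is a thresholded similarity, not an inferred network.
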