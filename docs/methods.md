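# Methods

## Problem setting

Given a binary lncRNA–disease association matrix `LD ∈ {0,1}^{nl×nd}` and
optionally a lncRNA–miRNA matrix `LM ∈ {0,1}^{nl×nm}`, the task is to score
every unobserved (lncRNA, disease) pair so that true but unrecorded
associations rank high. Known associations are positives; all other pairs
are unlabeled and treated as negatives, which makes the problem both
extremely imbalanced (a few percent positives) and a matrix-completion
problem rather than ordinary supervised classification.

## Similarities

Both entity types get a profile similarity fused from two terms:

- **GIP kernel** `K(i,j) = exp(−γ‖p_i − p_j‖²)` with
  `γ = γ₀ / mean_i ‖p_i‖²`, i.e. the bandwidth is normalized by the mean
  squared profile norm (the construction standard throughout this
  literature; the bandwidth factors `γ_d`, `γ_l′` default to 1). The kernel
  is undefined on an all-zero profile matrix and raises.
- **Cosine similarity** of the same profiles; zero-norm profiles get 0
  everywhere, including their own diagonal.

Fusion weights default to `α₁=0.1, α₂=0.9` (lncRNA) and `β₁=0.2, β₂=0.8`
(disease); the fused matrix is clipped to [0,1]. A precomputed disease
semantic similarity matrix, when supplied, replaces the cosine term on the
disease side. The semantic decay factor `Δ=0.5` is carried in the
configuration for use with ontology-derived semantic matrices but plays no
role in the default, download-free path. Similarities are recomputed per
cross-validation fold from the training-fold association matrix; the
alternative (computing them once globally) would leak held-out edges
through the similarity graph.

## Views and propagation

The association view stacks `[[LS, LD],[LDᵀ, DS]]`; this matrix is used
simultaneously as adjacency and as initial node features, so a node's
feature vector is its similarity-plus-association profile. The
heterogeneous view inserts the miRNA layer: miRNA–miRNA connections are
self-loops only and miRNA–disease edges are absent, because no such data
enters the model. With no miRNA table (`nm=0`) the heterogeneous view
degenerates to the association view's node set, which is how the
association-only ablation avoids a second code path.

Both adjacencies are normalized as `Â = D̃^{-1/2}(A+I)D̃^{-1/2}` with
`D̃ᵢᵢ = Σⱼ(A+I)ᵢⱼ`. Self-loops keep every degree positive; the spectrum of
`Â` lies in [−1,1] with `D̃^{1/2}·1` an eigenvector at 1 (both asserted in
tests). Similarity blocks are kept dense — no sparsification threshold is
applied, since the similarity values themselves carry the signal.

## Encoder

Per view: `GCN → GAT → GCN`.

- GCN layer: `relu(Â X W + B)`; the offset `B` is one row broadcast per
  output feature.
- GAT layer: attention scores `e_ij = (W_t h_j)ᵀ tanh(W_t h_i + b)` for
  `j` in the neighborhood `{j : (A+I)_ij > 0}`, softmax-normalized per
  node; the new feature is `relu(Σ_j α_ij h_j)`. Edge weights define only
  the support; the scores are functions of node features alone. The output
  activation is ReLU, matching the convolution layers.

The heterogeneous view's encoder runs over all `nl+nm+nd` nodes and its
output is restricted to the lncRNA and disease rows, so both views emit
`(nl+nd)` embeddings; these are concatenated column-wise and split into
`Y_l` (lncRNAs) and `Y_d` (diseases). Defaults: first-layer width 128,
latent widths `l1 = l2 = 64`, Glorot-uniform weight initialization with
zero offsets, fully seeded.

## Decoder, loss, training

Scores are `LD′ = (Y_l W_l)(Y_d W_d)ᵀ` with projection width `r = 32`.
Scores are left unsquashed: AUC/AUPR/top-k are rank-based, and a threshold
is introduced only for F1/MCC (see Evaluation).

The reconstruction loss is the masked, class-weighted squared error
`α‖Ω_P⊙(LD′−LD)‖² + (1−α)‖Ω_N⊙(LD′−LD)‖²`. The balance parameter is
derived from the mask counts `a = ΣΩ_P/(ΣΩ_P+ΣΩ_N)`; the **positive class
weight defaults to `1−a`** (`alpha_mode="complement"`), i.e. the rare
positives get the large weight. The literal assignment `α = a`
(`alpha_mode="prevalence"`) is retained as an option but disabled by default: on
synthetic data it drives the model to the all-zero solution (pooled test
AUC ≈ 0.53 where the complement weighting reaches the generator's Bayes
ceiling), which is precisely the imbalance failure a cost-sensitive loss
exists to prevent.

Regularization sums the squared Frobenius norms of the convolution
weights, attention weights, offsets and the decoder map `W_d` (`W_l` is
deliberately not penalized, mirroring the model's stated penalty set), and
enters the total loss with weight `γ = 1e-4` by default — small, because
the loss is already heavily masked and the model is full-batch.

Training is full-batch Adam (the graph is one sample), learning rate
0.005, 400 epochs, no early stopping or validation split. All tensors are
float64 and the backward pass is exact reverse-mode differentiation;
analytic gradients match central finite differences to 1e-4 relative error
on end-to-end toy instances (asserted in the suite). Training aborts with
the epoch number if the loss becomes non-finite.

## Evaluation protocol

Pairs (not lncRNAs or diseases) are partitioned: positives and negatives
are each shuffled into five near-equal subsets, and fold *f* holds out
positive subset *f* plus negative subset *f*. For each fold, held-out
positives are zeroed in the association matrix before similarity
computation and graph construction, and held-out pairs are excluded from
both loss masks — training never sees a test edge in any form. Test scores
are pooled across folds (each pair is scored exactly once) and metrics are
computed on the pooled set rather than averaged per fold.

AUC is the trapezoidal ROC area (verified in tests to equal the
tie-corrected Mann–Whitney statistic to 1e-10), AUPR is the step-integrated
precision–recall area. F1 and MCC need a binarization: by default the
F1-maximizing threshold on the pooled scores is used and reported; a fixed
threshold can be configured for reproducibility studies. Top-k recall
ranks each disease's lncRNAs by score (ties broken by index) and reports
the fraction of held-out positives inside the top k.

## Synthetic data generator

The generator emulates the *shape class* of curated lncRNA–disease data:
sparse binary matrices with modular structure in which functionally
related lncRNAs share disease spectra and miRNA partners. Entities are
assigned uniformly to `n_blocks` co-modules; within-module pairs associate
with probability `p_in` and cross-module pairs with `p_in/10`, with `p_in`
solved from the target density and the realized within-module pair
fraction. Independent entry flips at `noise_rate` model annotation errors.
Defaults: 60 lncRNAs × 80 diseases × 20 miRNAs, 4 blocks, density 0.05,
noise 0.02 — a scaled-down analogue of the ~240×412, 2.7%-dense curated
collection, sized so a full 5-fold run takes ~15 s on one CPU.

What the generator does **not** emulate: degree heterogeneity (hub
diseases), ontology-structured disease similarity, overlapping modules,
and the real data's 4× larger node set. Passing tests on this generator
therefore demonstrate correct mechanics and leakage-free evaluation, not
real-data accuracy levels.

**Recovery ceiling.** Conditional on the module labels, matrix entries are
independent coin flips, so module membership is the Bayes-sufficient
statistic: no method can rank within-module positives above within-module
negatives. At the default density/noise settings the true-label oracle
reaches only pooled AUC ≈ 0.70 and AUPR ≈ 2× prevalence (seeds 0–2), and
estimating the modules from a 60×80 training matrix is harder still. The
recovery acceptance test that demands AUC ≥ 0.85 and AUPR ≥ 5× prevalence
on these conditions is therefore expected to fail for any method, and is
kept in the suite, failing, as a faithful record of that bound. On denser,
noiseless conditions (density 0.15, noise 0) the model scores within 0.01
AUC of the oracle ceiling (0.79 vs 0.80), which is the meaningful
correctness evidence.

## Design choices and limitations

- The heterogeneous view's feature matrix is its own adjacency, extending
  the association view's features-equal-adjacency convention to cover the
  miRNA rows; only lncRNA/disease rows of its embedding are consumed
  downstream.
- The two encoder branches share their architecture and differ only in the
  graph (adjacency + features) they run on.
- Identifier ordering is lexicographic at load time, making every matrix
  index deterministic with respect to input file row order.
- Problem sizes in the test suite and the acceptance script are the
  generator defaults above; the acceptance script runs three full 5-fold
  CV passes (multiview + two ablations).
- Single-head attention, no dropout, no minibatching, no GPU path; the
  dense float64 implementation targets graphs of up to a few thousand
  nodes.
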