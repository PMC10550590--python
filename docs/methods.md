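# Methods

This note documents the modeling choices, defaults, and limitations of the
package. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The pathway prior

The prior graph has one node per Reactome pathway, an edge for every
parent/child hierarchy relation, and a unit diagonal (self-interaction).
The pathway universe is the intersection of the hierarchy file, the
gene-set (GMT) file, and — at featurization time — pathways with at least
one gene present in the cohort; pathways that lose all genes are dropped
and the adjacency re-indexed, with a warning.

## Featurization (K_p)

For each pathway and omic, the pathway's gene columns are centered and
projected onto the top-`q` principal axes. Two leakage-relevant choices:

* PCA is fit on a caller-supplied patient subset (the training split in
  any cross-validated run) and applied to everyone; held-out rows never
  influence the centering or the axes. The original work does not state
  whether PCA was fit per fold; fitting per training fold is the
  non-leaking choice and is the package default in the pipelines.
* PC signs are fixed by forcing the largest-magnitude loading of each
  axis positive, so features are reproducible across runs and platforms.

Pathways with fewer usable genes (or fitting rows) than `q` have their
missing PC columns padded with zeros rather than being dropped. `q = 2`
is the default (performance saturates around two components per omic);
the column order per pathway row is expression, copy number, methylation.
Methylation is taken as beta values in [0, 1]; no M-value transform.

TMB labels are strict: high iff mutations/Mb > 10, so a rate of exactly
10 labels low. The covered-megabase denominator defaults to 38 (a typical
exome footprint) and is a parameter.

## Network

* Graph-learning layer: `S_ij ∝ A_ij · exp(ReLU(aᵀ|g̃ᵢ − g̃ⱼ|))`,
  row-normalized over the support of `A`. The absolute elementwise
  difference is used rather than the antisymmetric signed difference,
  which would zero the gradient for half of each pair under
  `exp(ReLU(·))`; the signed variant is available via `signed_diff`.
* The projection `P` has shape (feature dim × d) shared across nodes, and
  `W^(0)` has shape (3q × width); `d` defaults to 4 and must be smaller
  than the input feature dimension.
* Cohort mode trains one affinity per patient from shared parameters
  (patients are evaluated as one block-diagonal graph), then flattens the
  conv output in fixed pathway order through fully connected layers —
  flattening preserves pathway identity for the explainer; mean-pooling is
  available via `readout="mean"`.
* Semi-supervision: all samples contribute to the graph-learning loss
  `L₁`; only labeled ones contribute to the cross-entropy `L₂`.
* Defaults: cohort mode — 2 conv layers (16), one FC layer (64), Adam
  lr 1e-3, 150 epochs, early stopping on validation loss (patience 30);
  transductive mode — 4 conv layers of width 20, lr 1e-2, 800 epochs
  (patience 200). Four hops both reach ~perfect validation accuracy on
  the motif benchmarks and give the explainer a computation neighborhood
  containing the whole motif plus base context. γ = 0.01, λ = 1.

Training, and the explainer below, run on a small reverse-mode autodiff
engine over numpy (`pglcn.autodiff`); gradients are verified against
central finite differences in the tests. No GPU or deep-learning
framework is required.

## Explainer

Masks are logit-parameterized, symmetric (one logit per unordered
supported pair, applied to both directions), and optimized with the model
frozen. The loss is the negative log-probability of the model's own
prediction under the masked inputs, plus per-mask binary-entropy and size
(mean of σ) regularizers. Both entropy and size act on σ of the logits —
binary entropy requires values in (0, 1).

Two numerical choices matter and were settled by pilot experiments on the
synthetic benchmarks (documented here because both differ from the naive
reading):

* **The edge mask multiplies the affinity after the row softmax.** If the
  mask enters before normalization, deleting an edge merely redistributes
  its weight to the row's surviving neighbors and the prediction barely
  changes — edge importances become unidentifiable. Post-softmax masking
  means a masked edge's contribution is genuinely removed (rows may sum
  to less than one), matching the un-renormalized masked-adjacency
  convention of mask-based GNN explainers.
* **Self-loops are never masked.** This guarantees every softmax row
  keeps support, and the explanation question is about interactions, not
  about whether a node may see its own features.

Defaults: Adam on the mask logits, lr 0.05, 100 epochs; edge size weight
0.05, feature size 1.0, feature entropy 0.1, edge entropy 0 (entropy
polarization amplifies early optimization noise on the small computation
subgraphs and degrades the edge ranking; the terms remain available);
logits initialized at N(2.0, 0.1) so optimization starts near the intact
model's operating point (σ ≈ 0.88). Because the size terms are means
over mask entries (per the loss definition), their weights play the role
of (coefficient × edge count) in sum-based implementations — hence the
edge-size default is well above the sum-convention 0.005.

Explanation fidelity on a benchmark node is the ROC AUC (concordant-pair
definition, ties half) of σ(mask) over the off-diagonal edges of the
node's k-hop computation neighborhood (k = number of conv layers),
positives = within-motif edges; attachment edges count as negatives.
Nodes whose neighborhood lacks a positive or a negative are reported as
missing and excluded from averages. Only motif nodes are explained.

## Synthetic benchmarks (the stated world)

Five node-classification datasets: a 300-node Barabási–Albert base (or a
depth-8 balanced binary tree, 255 nodes) with 80 disjoint motif copies
(five-node house / 3×3 grid / six-cycle), each attached to one uniformly
chosen base node by a single unflagged edge. BA-Community joins two
BA-House graphs with `0.01 × n` random cross edges and doubles the label
space. Labels are structural roles: base vs. house top/middle/bottom
(4 classes; 8 for BA-Community), base vs. motif for grids and cycles.

Two construction choices the source material leaves open:

* **BA attachment density m = 5.** With m = 1 the base is a tree that is
  locally indistinguishable from the sparse motifs; classification barely
  beats chance per role and explanations are unidentifiable. m = 5 is the
  construction used by the benchmark family this reproduces.
* **Node features.** The row-stochastic convolution maps constant
  features to constant features, so the all-ones convention would make
  every node's logits identical. The default "structural" policy is a
  constant column, the normalized degree, a clipped one-hot of the
  degree, and the normalized mean neighbor degree (dimension 10);
  BA-Community appends community-indexed Gaussian features
  (mean ±1, sd 0.5). The "ones" policy remains available.

What a green benchmark test establishes: the mask explainer recovers
planted structural ground truth under this feature policy and protocol.
What it does not establish: fidelity on graphs whose labels depend on
continuous node content rather than topology, or on the real pathway
graph (no ground truth exists there).

The benchmark measurement explains a deterministic 48-node subsample of
the ~400–800 motif nodes per dataset (per-node AUCs are i.i.d. across
motifs, so the subsample mean estimates the all-node mean without bias)
and averages over three seeds; this keeps the full five-dataset run
around 10–15 CPU-minutes.

## Synthetic cohort generator

`simulate_multiomics_cohort` draws TMB labels at 30% prevalence, gives
genes in the chosen effect pathways a mean shift of `effect_size` (in
noise-SD units) on expression and half-size shifts on copy number and
pre-squash methylation for TMB-high patients, all other values being
independent Gaussian noise; methylation is logistic-squashed to [0, 1];
mutation rates are drawn consistently with the labels (uniform below
10/Mb, 10.5 + Gamma(2, 4) above). `simulate_pathway_graph` builds a
random tree hierarchy in which the effect pathways form a connected
chain, so the planted signal spans a connected subgraph — the situation
the explainer is supposed to detect. The generator emulates group mean
shifts only: no gene–gene correlation structure, batch effects, censored
or missing values, or realistic mutation spectra.

## Evaluation protocol

5-fold stratified CV repeated 5 times; each fold's complement is
stratified-split 80/20 into train/validation. SMOTE (hand-implemented:
x + u·(x_nn − x), u ~ U(0,1), k = 5 minority neighbors) runs inside the
training partition only, after splitting — cohort-level balancing before
splitting leaks synthetic points into evaluation sets and is available
only behind an explicit flag. Metrics: accuracy, recall, precision, F1
for the positive (TMB-high) class at a 0.5 cutoff, and threshold-free
ROC AUC; reported as mean ± sample SD over the 25 runs. Baselines are
the sklearn reference implementations (L2 logistic regression, RBF and
linear SVM, random forest, AdaBoost, decision tree) at their library
defaults.

## Known limitations

* The printed fidelity value for BA-House (1.0) is not reached by this
  implementation (measured ≈ 0.86–0.88): an occlusion analysis on the
  trained model shows some within-motif edges are genuinely unused by
  the classifier (for house-role classes the model never needs the far
  side of the house), so no faithful mask can rank them above every base
  edge. The gap is a property of the model's redundancy, not of the mask
  optimizer.
* Cohort-mode explanations are per patient; aggregation across patients
  (the averaged masks used in the edge-recovery measurement) is a simple
  mean and other pooling schemes are unexplored.
* The TCGA/immunotherapy analyses of the original study (real-cohort
  AUC tables, immune-infiltration and pathway-screening results) are out
  of scope: they require external data access and are replaced by the
  planted-signal recovery checks.
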