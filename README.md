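# pglcn

A biologically informed graph neural network for classifying tumor
mutation burden (TMB) status from multi-omics data, with built-in
mask-based explanations and the synthetic motif-graph benchmarks used to
measure how faithful those explanations are.

## Who this is for

Computational oncology groups who want to (a) predict whether a tumor is
TMB-high (strictly more than 10 somatic mutations per megabase — a common
immunotherapy-response biomarker) from expression, copy-number and DNA
methylation profiles, and (b) ask *which pathway interactions* drove each
prediction, rather than treating the classifier as a black box.

## The model

Every patient is represented as a graph over Reactome pathways. Nodes are
pathways; the fixed prior adjacency `A ∈ {0,1}^{p×p}` connects parent/child
pathways in the Reactome hierarchy (unit diagonal). Node features are the
patient's pathway-level multi-omics profile `K_p ∈ R^{p×3q}`: for each
pathway and each omic (expression `G`, copy number `C`, methylation `M`),
the pathway's gene columns are reduced to their top `q` principal
components, ordered expression / CNV / methylation (so `q = 2` gives six
columns per pathway).

Three trainable stages:

1. **Graph learning.** Features are projected, `g̃ᵢ = gᵢ P`, and a
   row-stochastic affinity is learned over the support of the prior:

       S_ij = A_ij · exp(ReLU(aᵀ|g̃ᵢ − g̃ⱼ|)) / Σ_j A_ij · exp(ReLU(aᵀ|g̃ᵢ − g̃ⱼ|))

   trained with `L₁ = Σ_ij ‖gᵢ − gⱼ‖² S_ij + γ‖S‖_F²` — distant nodes are
   pushed to low affinity, the Frobenius term controls sparsity.
2. **Simplified graph convolutions** `X^(k+1) = σ(S X^(k) W^(k))` (no extra
   normalization — S is already row-stochastic), followed by a fully
   connected head to the class logits.
3. **Joint objective** `L = L₁ + λ L₂` with `L₂` the cross-entropy over
   labeled samples.

To explain a prediction, the trained network Φ is frozen and an edge mask
`M` and feature mask `F` are optimized so that Φ evaluated on
`E ⊙ σ(M), X ⊙ σ(F)` preserves the original prediction while the masks
stay small; `σ(M)` then scores each pathway edge's importance. On the five
synthetic benchmarks (BA-House, BA-Community, BA-Grid, Tree-Cycles,
Tree-Grids) the planted motif edges are known ground truth, and fidelity
is the ROC AUC of mask weights against them.

Because no external cohort is required, the package ships a synthetic
multi-omics cohort generator with planted pathway-level group differences,
used throughout the tests.

## Worked example

```python
import numpy as np
from pglcn import (simulate_pathway_graph, simulate_multiomics_cohort,
                   pathway_pca_features, cohort_recovery)

r = cohort_recovery(seed=1)   # simulate -> featurize -> train -> explain
print(f"test AUC {r['test_auc']:.3f}")
print(f"edge-recovery AUC {r['edge_recovery_auc']:.3f}")
```

prints

```
test AUC 1.000
edge-recovery AUC 0.956
```

meaning: on a 400-patient synthetic cohort where ten connected pathways
carry a mean shift of 2 SD in the TMB-high group, the trained network
separates TMB-high from TMB-low test patients perfectly (ROC AUC 1.0),
and the averaged explanation edge masks rank pathway-pathway edges inside
the planted module above background edges with AUC 0.956 — the explainer
points at the right part of the pathway graph.

The same pipeline is scriptable from the shell:

```bash
pglcn bench generate --name BA-House --seed 0 --out out/bahouse
pglcn bench run --names BA-House,Tree-Cycles --seeds 0,1,2 --out out/fidelity
pglcn simulate --n-patients 400 --seed 0 --out out/sim
pglcn featurize --cohort out/sim --relations out/sim/relations.tsv \
      --gmt out/sim/genesets.gmt --q 2 --out out/feat
pglcn evaluate --features out/feat/features.npz --models pglcn,logreg,rf \
      --seed 0 --out out/metrics.tsv
```

Real data drop in the same way: a Reactome relation file
(`ReactomePathwaysRelation.txt` dialect), a GMT gene-set file, and
patient×gene TSV matrices for the three omics.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the five synthetic benchmarks over three seeds, trains the
node classifier on each, fits per-node edge masks for a 48-node subsample
of motif nodes, and writes the per-dataset mean explanation AUC
(`t1`…`t5`) as JSON. Runtime is roughly 10–15 minutes on one CPU.

## Layout

| module | contents |
| --- | --- |
| `pglcn.benchmarks` | the five motif-graph benchmark generators + bundle I/O |
| `pglcn.pathway` | Reactome hierarchy/GMT parsing, per-pathway PCA features, TMB labels, cohort simulator |
| `pglcn.model` | graph-learning layer, convolution stack, losses, training loops |
| `pglcn.explainer` | edge/feature mask fitting, explanation AUC, subgraph extraction |
| `pglcn.evaluation` | SMOTE, repeated stratified CV, metrics, baseline comparison |
| `pglcn.pipeline` | end-to-end drivers (benchmark suite, cohort recovery) |
| `pglcn.cli` | `pglcn` command-line entry point |

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
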