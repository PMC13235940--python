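# geneprog

Supervised gene-program learning for single-cell expression data, guided by
a gene–gene functional-annotation graph.

## The problem

Cell-by-cell differential expression on modern scRNA-seq cohorts returns
thousands of "significant" genes with negligible effect sizes. When the
scientific question is *which coherent gene sets distinguish a phenotype*
(severe vs. mild disease, responder vs. non-responder), a more useful object
is a small number of **gene programs**: sparse, functionally coherent gene
sets whose pooled expression classifies cells — and, after averaging cell
scores within each donor, classifies individuals.

`geneprog` learns such programs with a graph neural network over a
protein–protein interaction (or any other) gene–gene graph, jointly with
the classifier that uses them.

## The model

Let `X ∈ R^{p×n}` be the transposed expression matrix of the `n` training
cells over `p` genes, and `A ∈ R^{p×p}` the symmetric annotation adjacency
with self-connections, normalized as `Ã = D^{-1/2} A D^{-1/2}`. A two-layer
graph-convolution encoder

```
H(1) = ReLU(Ã X W + X W_skip),   H(2) = ReLU(Ã H(1) W(1) + H(1) W_skip(1))
```

feeds a row-wise softmax pooling step `S = softmax(H W_H) ∈ R^{p×d}`, the
**loading matrix** mapping `p` genes onto `d` programs (rows sum to 1).
Cells are projected into program space, `X_r = Xᵀ S`, and classified by an
MLP (three hidden layers of 64 ReLU units, dropout 0.5). The joint objective
is

```
L = L_clf + w · (L_c + L_o)
```

where `L_clf` is the cross-entropy of the classifier,
`L_c = −Tr(SᵀÃS)/Tr(SᵀD̃S) ∈ [−1, 0]` is a minCUT-style penalty that pools
strongly connected genes together, and `L_o = ‖SᵀS/‖SᵀS‖_F − I_d/√d‖_F`
pushes loadings toward balanced, near-one-hot assignments. The weight `w`
(default 2) balances annotation coherence against raw predictive fit; at
`w = 0` the method reduces to an annotation-free softmax-pooled MLP.

Because `S` depends on genes, not cells, a trained loading matrix transfers
to external datasets: gene lists are aligned and the shared submatrices of
the data and `S` are used for projection. Donor-level prediction is the
unweighted mean of a donor's cell-level scores.

Interpretability diagnostics include per-gene Hoyer sparsity of loading
vectors, thresholded gene sets (loading > 0.8), and each set's connectivity
quantile against random same-size gene sets in the annotation graph.

## Worked example

Simulate a multi-donor cohort with five planted 20-gene modules (three of
them phenotype-associated), train with `w = 2` and `d = 10` programs at
desk scale, and inspect the result:

```python
import numpy as np
from geneprog import (SimConfig, TrainConfig, generate, normalize_log,
                      extract_gene_sets, auc)
from geneprog.training import fit
from geneprog.inference import predict

sim = SimConfig(n_genes=300, n_modules=5, module_size=20,
                n_donors_per_class=8, cells_per_donor=25,
                p_in=0.3, p_out=0.01, effect_size=2.0, seed=1)
data = generate(sim)
norm = normalize_log(data.expression)

cfg = TrainConfig(w=2.0, d=10, learning_rate=1e-3,
                  max_epochs=2000, min_epochs=500, patience_epochs=300, seed=1)
model = fit(norm, data.graph, cfg)

sets = extract_gene_sets(model.loading, model.gene_list, threshold=0.8)
print(f"non-empty programs: {sets.non_empty_count} / {cfg.d}")
for s in sets.non_empty()[:3]:
    q = s.connectivity_quantile(data.graph, n_null=1000, seed=0)
    print(f"  program {s.program}: {s.size} genes, "
          f"connectivity {s.connectivity(data.graph):.2f}, quantile {q:.3f}")

test = norm.subset_cells(norm.split_mask("test"))
table = predict(test, model)
print(f"individual-level AUC: {auc(table.individuals['score'], table.individuals['label']):.3f}")
```

Output:

```
non-empty programs: 10 / 10
  program 0: 28 genes, connectivity 5.07, quantile 1.000
  program 1: 28 genes, connectivity 1.29, quantile 0.999
  program 2: 29 genes, connectivity 4.97, quantile 1.000
individual-level AUC: 1.000
```

All ten programs carry genes; their members are far more connected in the
planted graph than random same-size sets (quantiles ≈ 1), and the averaged
cell scores separate the held-out donors perfectly. On real data the same
quantities are the ones to watch when choosing `w`: validation performance,
the number of non-empty programs, and the connectivity quantiles
(`geneprog sweep-w`, or `geneprog.training.sweep_w` / `select_w`).

The same workflow is available from the shell:

```
geneprog simulate --out data/ --seed 1
geneprog fit data/ data/graph_edges.tsv --out model/ --w 2 --d 10
geneprog predict model/ data/ --out scores/
geneprog evaluate model/ data/graph_edges.tsv --out diag/ --predictions scores/
```

For real cohorts, `fit` accepts an MTX+TSV directory or an h5ad file plus a
BioGRID TAB3 interaction export (or any 2/3-column edge list), and runs
marker-gene preselection (one-sided Mann–Whitney per class, BH FDR ≤ 0.05,
top-1000 by normalized variance per class) before training.

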