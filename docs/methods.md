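# Methods

## Model and assumptions

`geneprog` treats each gene as a node of an annotation graph whose node
features are that gene's expression across the training cells. The method
assumes (i) that phenotype-relevant transcriptional signal is organized
into groups of genes that are both co-expressed and adjacent in the
annotation graph, and (ii) that cell-level labels inherited from donor
phenotypes are informative on average even when individual cells are
mislabeled by within-donor heterogeneity.

The encoder applies two graph-convolution layers with skip terms,

    H(1) = ReLU(Ã X W + X W_skip),    H(ℓ) = ReLU(Ã H(ℓ−1) W(ℓ−1) + H(ℓ−1) W_skip(ℓ−1)),

with `Ã = D^{-1/2} A D^{-1/2}` the symmetrically normalized self-looped
adjacency, followed by row-softmax pooling `S = softmax(H W_H)`. The
classifier is an MLP with three 64-unit ReLU hidden layers and dropout 0.5
after each hidden layer (never after the output). The joint loss is
`L_clf + w (L_c + L_o)` with

    L_c = − Tr(SᵀÃS) / Tr(SᵀD̃S),      L_o = ‖ SᵀS/‖SᵀS‖_F − I_d/√d ‖_F,

where `D̃` is the degree matrix of `Ã`. `L_c` lies in `[−1, 0]` for any
row-stochastic `S`; its minimum is attained when pooled groups capture all
normalized edge mass. `L_o` vanishes exactly at balanced one-hot loadings,
which is what makes near-binary, comparable-size programs the optimum of
the combined graph term.

**Orthogonality-target convention.** The penalty's target matrix is
`I_d/√d` by default (the standard minCUT orthogonality target): only with
the `1/√d` scaling is balanced one-hot pooling an exact minimizer. A plain
`I_d` variant is selectable via `ortho_target="identity"` for comparison;
it shifts the minimum away from one-hot loadings and is not recommended.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `d` (`n_programs`) | 40 | number of gene programs (columns of S) |
| `h` (`hidden_units`) | 64 | conv-layer width; two layers |
| `w` | 2.0 | weight of the graph loss; 0 disables annotation guidance |
| `learning_rate` / `weight_decay` | 1e-4 / 1e-4 | Adam settings (full-batch) |
| `max_epochs` / `min_epochs` / `patience` | 50 000 / 10 000 / 3 000 | early-stopping envelope |
| `dropout` | 0.5 | MLP-head dropout (training only) |
| `validation_fraction` | 0.1 | stratified hold-out for early stopping |
| loading threshold | 0.8 | strict lower bound for set membership |
| `n_null` | 1000 | null samples per connectivity quantile |
| `target_sum` | 10 000 | per-cell depth normalization before log1p |

The defaults reproduce the reference operating point. Test- and
example-scale runs in this repository use `learning_rate=1e-3` with
`max_epochs ≤ 2000`, `min_epochs=500` and `patience=300`; on the synthetic
fixtures these reach the same qualitative optimum (near-one-hot loadings,
recovered modules) in minutes on one CPU, which we verified against the
planted ground truth rather than against longer runs.

**Choosing w.** `sweep_w` fits one model per grid value (default
{0, 0.25, 0.5, 1, 2, 5, 10}) and tabulates validation performance,
non-empty program count and mean connectivity quantile; `select_w` returns
the smallest `w` whose validation metric is within an absolute tolerance
(default 0.02) of the best. Diagnostics generally stabilize well before
validation performance starts to degrade, which is why the smallest
adequate `w` is preferred.

## Numerical choices

- **Node-feature centering.** Expression features are nonnegative, so all
  genes share a dominant positive mean direction; fed raw into the
  encoder, the pooled representations of all genes are nearly collinear
  and the loadings collapse into a single program (a degenerate minimizer
  of `L_c` at exactly −1, from which saturated softmax gradients cannot
  escape). The estimator therefore centers each gene's feature vector
  across training cells before the encoder (`center_features=True`).
  Projection (`X·S`), scoring and transfer always use raw log-normalized
  values; centering conditions only the encoder input.
- **Softmax** is computed with row-max subtraction; results equal the
  mathematical softmax.
- The denominator of `L_c` is guarded at 1e-12; falling below it raises a
  degenerate-pooling error rather than silently producing huge gradients.
- Early stopping monitors the **validation classification loss only**
  (default): the graph terms are cell-independent, so including them
  (available via `early_stopping_metric="total"`) only shifts the curve by
  a training-state constant. Improvement means strictly lower than the
  running best; parameters are restored to the best epoch.
- Validation cells are excluded from the encoder's node features (the
  first-layer weights are shaped by training cells only), preventing
  leakage of held-out cells into representation learning.
- All randomness (init, splits, dropout) derives from one seed through
  independent substreams; equal seeds give bit-identical fits.
- Weight decay is folded into the Adam gradient (the coupled formulation),
  matching the common deep-learning-framework default.
- Self-loop weights are 1 for binary graphs and the maximum edge weight
  for weighted graphs, keeping self-influence comparable to the strongest
  neighbor. Degrees are weighted row sums.
- Mann–Whitney p-values are exact (full enumeration) when both groups have
  ≤ 8 tie-free observations and use the tie-corrected normal approximation
  otherwise. HVG "normalized variance" is the per-gene variance of
  depth-normalized log1p expression across training cells; ties in the
  variance ranking break lexicographically by gene symbol.
- Connectivity counts an edge between distinct set members when its weight
  is positive (a weighted-sum variant is available); self-loops are a
  normalization device and are excluded. Null sets for the quantile are
  drawn uniformly without replacement from the graph's gene universe, and
  ties use the mid-rank convention — an exchangeable set therefore lands
  at 0.5 rather than at an arbitrary extreme.
- Gene-list transfer uses the plain submatrix of `S` for shared genes;
  rows are **not** renormalized after subsetting (a `renormalize` option
  exists, default off). Missing genes contribute nothing to the
  projection.
- Graph perturbation removes a fraction of off-diagonal edges and redraws
  the same number uniformly from pairs absent after removal, preserving
  edge count and self-loops — a sensitivity utility, not a claim of exact
  replication of any particular published perturbation protocol.

## The synthetic generator

`SimConfig`/`generate` emulate the structure the learner assumes: genes
are partitioned into modules that are densely connected in the graph
(`p_in` within, `p_out` between, self-loops everywhere); each module has a
per-cell activity `a ~ Normal(μ_class, 1)`, with informative modules
shifting `μ` by `effect_size` in the positive class; a gene's count is
`Poisson(10 · exp(a + Normal(0, noise_sd)))`, giving right-skewed integer
counts whose planted structure is linear after log transform. Donors carry
the class label; a `cell_label_noise` fraction of each donor's cells draws
activities from the opposite class, mimicking labels inherited from donor
phenotypes. Splits are assigned at the donor level (default half the
donors per class held out for testing), so test AUC is measured on unseen
individuals.

What the generator does **not** emulate: dropout/zero inflation beyond
Poisson sampling, batch effects, multiple cell types, gene–gene
correlation that is not module-structured, and realistic annotation-graph
degree distributions (hubs). Passing tests on these fixtures therefore
demonstrate correctness of the machinery and recoverability under the
stated model, not performance on real cohorts.

A side effect worth knowing: shifting informative modules up in one class
raises those cells' library sizes, so after depth normalization all other
genes acquire a small opposite-direction shift. The marker-preselection
step consequently selects many genes in both directions on these fixtures
— intentional behaviour of one-sided per-class testing under
compositional normalization.

## Design decisions taken where the design was open

- The core is a scikit-learn-style estimator (`GeneProgramClassifier`)
  with `fit`/`predict_proba`/`transform` and fitted attributes
  (`loading_`, `history_`, …); dataset-aware wrappers in
  `geneprog.training` carry gene lists, split tags and serialization.
- The optimizer, autodiff and training loop are implemented in numpy
  (`geneprog/_autodiff.py`): the model is small and fixed, full-batch, and
  CPU-bound; gradients are verified against finite differences in the
  test suite.
- BioGRID parsing uses only the two official-symbol columns,
  case-sensitively after whitespace trimming, with no alias resolution
  and no filtering by experimental system; isoform-level records collapse
  to one gene-level edge.
- The per-class HVG variance is computed across **all training cells**
  (not class cells only), matching the inclusive intent of preselection.
- The empty-selection error (no gene passes FDR in any class) is
  deliberate: a null dataset should fail loudly at preselection, and
  annotation-free/no-selection runs are available via `skip_selection`.

## Known limitations

- Full-batch training ties the first conv layer's parameter count to the
  number of training cells; very large cohorts need subsampling upstream.
- Only single-level pooling is implemented (no hierarchical programs) and
  one cell type at a time; multiclass and regression heads are provided
  but donor aggregation of regression outputs is a plain mean.
- Probability calibration is out of scope; scores are logistic outputs.
- Connectivity quantiles are Monte-Carlo estimates; with very small
  universes use the exhaustive enumeration in the tests as reference.
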