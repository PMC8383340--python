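# Methods

## Model

`resmnn` corrects batch effects by learning a map Y = f(X) from scaled
expression to corrected expression, where f is a stack of two residual
blocks. Each block computes y = x + δ(x); δ is two sequences of
affine → batch-normalization → PReLU layers, the first affine widening
d → 2d and the second narrowing 2d → d. Nothing follows the residual
addition. The working assumption is the usual MNN one: the batch effect is
(locally) an additive displacement approximately orthogonal to the
biological manifold, so cross-batch mutual nearest neighbors in PCA space
are predominantly the same cell state, and pulling them together removes
the technical displacement rather than the biology. The residual
parameterization encodes the prior that the correction is a perturbation of
the identity: with δ = 0 the network is exactly the identity map, and what
it learns in δ is the batch effect itself.

The objective is L = L_b + α·L_r with L_b the sum of Euclidean distances
between the two members of each MNN pair after projecting the network
output through the PCA loadings fit on the *input* (the loadings stay
frozen; gradients flow only through Y), and L_r the sum of per-cell
Euclidean distances between output and input. L_b alone has a degenerate
optimum (collapse everything to a point); L_r anchors the output to the
input and sets the trade-off via α.

## Pipeline and parameters

| parameter | default | meaning |
|---|---|---|
| scale | 10,000 | per-cell total after normalization (counts) |
| n_hvg | 2,000 | highly variable genes kept (mean-binned normalized dispersion on log data) |
| clip | 10 | upper z-score clip; `symmetric=True` also clips at −10 |
| n_pc | 50 | PCA components used for MNN search and the batch loss |
| k | 20 | neighbors per cell in the cross-batch kNN queries |
| α | 0.001 | regularization weight (unitless ratio of the two loss sums) |
| lr schedule | 0.1 × 0.8^⌊epoch/20⌋ | Adam step size |
| minibatch | 1,024 MNN pairs | both members forwarded per step |
| max_epochs / patience | 200 / 10 | early stop on non-improving epoch loss |

Design choices where more than one reading was defensible:

* **Minibatch unit.** The batch size counts MNN *pairs*; the
  regularization term of a step covers the distinct cells appearing in the
  step's pairs, keeping both loss terms on the same sample. A
  `reg_scope="all_cells"` option additionally folds a per-epoch permutation
  slice of all cells into each step as regularization-only rows, so cells
  outside any pair also contribute to L_r once per epoch. Cells in no pair
  are still corrected at inference (the forward pass applies to everyone).
* **Projection centering.** The loss projection subtracts the PCA center
  before multiplying by the loadings, for consistency with the input
  embedding (an uncentered variant is available via
  `center_projection=False`; it only shifts both pair members equally, so
  L_b is in fact identical either way).
* **Batch normalization.** Momentum 0.1, eps 1e-5; batch statistics use the
  population (ddof = 0) variance for both the normalization and the running
  averages; inference uses running statistics, applied to all cells at
  once, so inference is a pure function. PReLU uses one learnable slope per
  activation layer, initialized at 0.25. Weights and biases initialize
  uniformly in ±1/√fan_in from a seeded generator.
* **Early stopping.** The epoch loss is the sum of minibatch total losses;
  "no improvement" means not strictly below the best epoch loss so far;
  after 10 such epochs training stops and the best-epoch parameters
  (including running statistics) are restored.
* **HVG ranking** follows the standard mean-binned normalized-dispersion
  ("seurat-flavor") criterion via scanpy; PCA fits on the post-clip matrix
  (clipping slightly shifts gene means; we center on what the network
  actually sees) with each component's sign fixed so its largest-magnitude
  loading is positive, making runs reproducible.
* **MNN search** runs per ordered batch pair rather than against the pooled
  complement: pooling lets a large batch crowd out small ones and makes
  mutuality ill-defined for >2 batches. Search is exact (scikit-learn) for
  small batches and switches to seeded NN-descent above 1,000 cells per
  batch; an explicit `method=` override exists, and tests/validation use
  exact mode so results are approximation-free. When a batch holds fewer
  than k cells, k truncates to the batch size. Pairs are computed once,
  before training, not refreshed during it.

## Evaluation metrics

Batch entropy and cell-type entropy are computed per cell from the label
composition of its 20 exact nearest neighbors:
E_i = −(1/M)·Σ_m P_im ln P_im with M the number of batches (or types). The
maximum, ln(M)/M, is reached at a uniform neighborhood; 0·ln 0 := 0;
natural logarithm throughout (the base rescales values, not orderings).
Full per-cell distributions are kept and medians reported.

ARI F1: per replicate, 80% of cells are drawn without replacement, k-means
(k = number of cell types present in the subsample, 10 seeded restarts)
clusters the embedding, and the adjusted Rand index of the clustering
against the batch and the cell-type labeling is rescaled to [0,1] via
(ARI+1)/2 — the only label-free linear map of the theoretical range — and
combined as F1 = 2(1−a_b)a_c/(1−a_b+a_c). ASW F1 applies the same protocol
with average silhouette widths under the two labelings (no clustering
step), also rescaled by (ASW+1)/2. 20 replicates each, seeds derived from a
master seed via a seed sequence; singleton-cluster silhouettes are 0 by
convention. The plain Rand index and entropies are computed from their
defining formulas; ARI, silhouettes, k-means and exact kNN go through
scikit-learn, and every metric is cross-checked in the test suite against
independent scalar-loop oracles. Replicate vectors are exported so any
statistics package can run significance tests on them; no testing harness
is built in.

## Synthetic data

Each cell type t is a point μ_t in a 10-dimensional latent "program" space
(coordinates i.i.d. N(0, separation²), separation 1 by default), mapped to
gene log-means through a fixed random loading matrix scaled by 1/√dim.
Batch b adds a shift β_b ~ N(0, shift²) per gene in log-mean space;
`type_specific_shift` optionally adds a type-by-batch interaction to
stress-test the orthogonality assumption. Per-cell rates are the softmaxed
log-means times a log-normal library size (mean 5,000, σ 0.25), and counts
are negative-binomial via a gamma-Poisson mixture with gene dispersion 0.1
— standard UMI-scale noise. The default shift (1.2) is chosen so that the
uncorrected embedding clusters primarily by batch, as raw cross-protocol
integration data does, while the shift direction remains near-orthogonal to
the low-dimensional biology (so cross-batch MNN pairs stay >80% same-type).

What the simulator does *not* emulate: protocol-specific dropout curves,
UMI saturation, ambient RNA, doublets, nonlinear (type-dependent, unless
requested) batch distortions, and continuous differentiation trajectories.
Passing tests therefore demonstrate that the implementation removes
additive-in-log-space batch structure while preserving discrete type
structure — not that it handles every pathology of real data.

Scenario presets: `identical` (2 × 1,500 cells, 5 shared types),
`nonidentical` (2 batches, 6 types, one private to each), `multibatch`
(5 unequal batches, 900–250 cells, 8 types, non-identical composition with
≥2 shared types per batch pair, pancreas-style), `large` (2 × 20,000).

## Numerical notes

* Training arithmetic is float32 (float64 available via the network's
  `dtype`; the finite-difference gradient validation uses it). Adam
  moments are kept in float64.
* Distance gradients guard the non-differentiable point: a pair (or cell)
  at distance exactly 0 contributes a zero subgradient.
* Zero-variance genes entering the z-score (possible only in degenerate
  inputs) have their SD replaced by 1, yielding all-zero z-scores rather
  than NaNs; zero-total cells are a named error and should be removed by QC.
* k in kNN graphs truncates to n−1; k in MNN queries truncates to the
  target batch size; k-means cluster counts follow the subsample's type
  census.
* Desk-scale problem sizes: the end-to-end validation runs and the
  reproduction script use the scenario presets' cell counts with 2,000
  simulated genes, 400 HVGs and 50 PCs, and cap training at 100 epochs —
  comfortably past the 50–100 epochs the optimizer typically needs on
  these scenarios while keeping a full run in minutes on one CPU. The
  defaults (2,000 HVGs, 200 epochs) are intended for real datasets.

## Known limitations

* MNN pairs are computed once in the raw PCA space; a severely distorted
  initial embedding yields mismatched pairs the network will then enforce.
* The correction is learned per dataset; the network is not transferable
  across datasets.
* Batch-norm running statistics make inference depend (deterministically)
  on the training trajectory; two different seeds give slightly different
  corrected embeddings.
* Checkpoints store raw arrays (`.npz`); no versioned schema.
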