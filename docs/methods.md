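# Methods

This note documents the modelling choices behind `hyperbroad`: what each
stage computes, which parameters matter, what the synthetic generator does
and does not emulate, and the numerical conventions.

## Pipeline

Each subject enters as a T×M table of ROI BOLD signals (rows = time
points). The stages are:

1. **Low-order FCN.** Pairwise Pearson correlation of ROI columns. No
   Fisher z-transform, no thresholding: raw ρ ∈ [−1, 1] flows downstream.
   The diagonal is forced to exactly 1 so that hypergraph distances are not
   perturbed by floating-point drift. A zero-variance ROI raises an error
   naming the ROI: a constant BOLD course is a data defect, not a zero
   correlation.
2. **Hypergraph Ho-FCN.** Every ROI is the center of one hyperedge
   containing itself plus its k nearest ROIs, so the incidence matrix H is
   M×M with column sums k+1 and every hyperedge degree is k+1. Distances
   are Euclidean between ROI *connectivity profiles* (rows of the subject's
   Lo-FCN) by default; raw time-series columns are available via
   `hypergraph.feature_space = "timeseries"`. Profiles are the default
   because they are scale-consistent across subjects — two subjects with
   different signal amplitudes still live in comparable [−1,1] correlation
   space — and because the high-order network is conceptually built *on*
   the low-order one. Ties in distance resolve to the lowest vertex index
   (stable sort), making construction platform-independent; duplicate
   hyperedges are retained so H stays M×M. Hyperedge weights default to 1
   (configurable); nothing in the method constrains them.
3. **Feature vector.** The normalized association
   S = D_v^{−1/2} H W D_e^{−1} H^T D_v^{−1/2} (equivalently I − Δ_norm) is
   vectorized over its strict upper triangle (length M(M−1)/2). S is the
   feature source because it is bounded, symmetric and directly comparable
   across subjects; Δ_norm and the raw incidence matrix are selectable
   alternatives (`hypergraph.matrix`).
4. **Autoencoder.** L tanh encoder layers and L strictly linear decoder
   layers (the decoder map is affine by construction; no nonlinearity),
   dimensions interpolating geometrically from the input to a bottleneck.
   Trained jointly (not greedy layer-wise) on mean squared reconstruction
   error. Inputs are z-scored per feature with training-fold statistics —
   tanh saturates on raw scales — and the same transform is applied to the
   held-out fold.
5. **BLS.** Random mapping-node groups, enhancement nodes on the
   concatenated mapping output, ridge closed form for the output weights,
   argmax decode of one-hot scores (ties toward the lexicographically
   earlier class). Random parameters are uniform on [−1, 1], the
   convention of the original broad-learning literature; they are never
   trained. The codes entering the BLS are z-scored with training-fold
   statistics for the same saturation reason.
6. **Cross-validation.** Class-stratified folds (per-class counts across
   folds differ by at most 1), reshuffled each repeat with a derived seed.
   Stratification is a deliberate strengthening of plain random splitting:
   it removes the possibility of a degenerate single-class fold.
   All sites/batches are pooled before folding. Metrics: accuracy,
   sensitivity (true-positive rate over the positive class), specificity,
   precision; a zero denominator reports NaN ("undefined"), never 0.
   Aggregation is mean ± sd over repeat×fold cells; count-pooled per-repeat
   metrics are also available and are the right choice for leave-one-out.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `hypergraph.k` | 5 | neighbours per hyperedge; the established operating point for this construction |
| `autoencoder.n_layers` | 3 | encoder depth |
| `autoencoder.bottleneck` | 512 | code size for ~20k-dimensional inputs (M ≈ 200); scale down with the feature dimension |
| `autoencoder.epochs / batch_size / learning_rate` | 200 / 32 / 1e-3 | Adam minibatch training; converges to within a few percent of the linear (PCA) reconstruction floor on desk-scale data |
| `bls.n_map_groups × nodes_per_group` | 20 × 100 | mapping layer (2000 nodes) |
| `bls.n_enh_groups × enh_nodes_per_group` | 1 × 10 | enhancement layer |
| `bls.ridge` | 1e-8 | near-interpolating ridge, stable because the Gram matrix is shifted |
| `cv.n_folds / n_repeats` | 10 / 10 | repeated stratified CV; results reported mean ± sd |

The autoencoder optimizer is Adam. Plain momentum-free SGD is available
(`optimizer="sgd"`) but is not the default: at desk scale (≈10²–10³
samples of ≈10²–10³ features) it leaves the reconstruction loss near the
trivial predict-zero baseline within any reasonable epoch budget, while
Adam reaches the PCA floor; an untrained encoder is just a random
projection and defeats the purpose of the reduction stage.

BLS node-count notation: the mapping layer is specified as
(number of groups) × (window size, nodes per group); enhancement nodes are
(groups) × (nodes per group) with one group by default. All four counts
are independent config keys, so either "total nodes" or "groups × window"
accounting is expressible.

## Synthetic data

The generator emulates multi-subject two-class ROI time series whose
classes differ in *module-level* coupling: ROIs are partitioned into
modules; within-module correlation is shared (0.6); between-module
correlation is 0.1 for controls and 0.5 for cases by default; subjects are
i.i.d. draws of T=150 time points from N(0, C_class) plus independent
observation noise (sd 0.2, which attenuates all correlations by
1/(1+sd²) ≈ 0.96). Defaults: 40 ROIs, 4 modules, 60 subjects per class.
These sizes exercise every stage (780-dimensional feature vectors, real
fold structure) while keeping a full repeated-CV run under a minute.

What it does **not** emulate: hemodynamic autocorrelation (time points are
i.i.d.), site/scanner effects, motion artifacts, heterogeneous module
sizes, or subject-level variability in connectivity (all subjects of a
class share one correlation matrix). Passing tests therefore show that the
pipeline recovers block-structured covariance differences and is correctly
calibrated under exchangeability — not that it attains any particular
accuracy on clinical data.

The canned experiment (`hyperbroad.experiments`) runs this generator at
the defaults with a pipeline configuration scaled to the 780-dimensional
features: bottleneck 64 and 60 epochs (the reconstruction loss plateaus
well before), BLS at 20×100 + 10. Null-calibration checks average three
dataset seeds × two fold-shuffle repeats; a single 10-fold run of 120
subjects has a per-dataset accuracy sd of about 0.05 under the null
(fold-assignment and classifier variance on top of binomial noise), so
averaging keeps the check well inside the N=120 binomial interval without
touching the interval itself.

## Numerical conventions

- Correlations are computed by `numpy.corrcoef`, symmetrized, clipped to
  [−1, 1]; the Laplacians are symmetrized as (A + Aᵀ)/2 to remove
  floating-point asymmetry before eigen-checks.
- The ridge system is solved as a symmetric linear system
  (A^TA + λI)W = A^TY; with λ > 0 the matrix is positive definite.
- Constant features in a training fold get unit scale in the z-score
  (they carry no information and map to 0).
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; per-fold seeds are derived from
  (cv.seed, repeat, fold), so any fold model is reproducible in isolation
  — that is also how the leakage test retrains a fold from training rows
  alone and demands bitwise-equal parameters.
- Training determinism is bitwise for fixed seeds on a given platform;
  cross-platform agreement is to BLAS summation order (1 ulp per dot
  product).

## Limitations

- The pipeline starts from extracted ROI signals; volume reading, atlas
  application and nuisance regression are out of scope.
- The autoencoder and BLS are trained per fold (no leakage). Published
  pipelines sometimes train representation learners once on all data;
  accuracies obtained that way are not directly comparable.
- Incremental/online BLS weight updates are not implemented — batch
  training only.
- With leave-one-out folds, per-fold sensitivity/specificity are mostly
  undefined; use the pooled per-repeat metrics.
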