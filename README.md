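# hyperbroad

Classification of brain functional networks from ROI time series, using
**hypergraph-based high-order connectivity** and **deep-broad learning**
(a stacked autoencoder followed by a Broad Learning System).

Resting-state fMRI studies of conditions such as autism spectrum disorder
usually summarize each subject by the *low-order* functional connectivity
network (Lo-FCN): the M×M matrix of pairwise Pearson correlations between
ROI BOLD signals. Pairwise correlations miss interactions that involve
several regions at once. This package lifts each subject's Lo-FCN to a
*high-order* network (Ho-FCN) through a hypergraph whose hyperedges connect
each ROI to its k nearest neighbours in connectivity-profile space, reduces
the resulting high-dimensional features with a stacked autoencoder, and
classifies subjects with a Broad Learning System (BLS) under repeated
stratified 10-fold cross-validation. A synthetic generator produces
two-class datasets with controlled between-module correlation differences,
so the whole pipeline is testable without access to clinical data.

## The model

For ROI time courses *u*, *v* of length *T*, the Lo-FCN entries are

ρ<sub>uv</sub> = Σ<sub>t</sub>(u<sub>t</sub>−ū)(v<sub>t</sub>−v̄) /
√(Σ<sub>t</sub>(u<sub>t</sub>−ū)² Σ<sub>t</sub>(v<sub>t</sub>−v̄)²).

A hypergraph G = {V, E, W} over the M ROIs is built by taking every ROI as
the center of one hyperedge containing the center plus its k nearest ROIs
(Euclidean distance between connectivity profiles; k = 5 by default). With
incidence matrix H, hyperedge weights W, vertex degrees D<sub>v</sub> and
hyperedge degrees D<sub>e</sub>, the hypergraph Laplacian is

Δ = D<sub>v</sub> − H W D<sub>e</sub><sup>−1</sup> H<sup>T</sup>,  
Δ<sub>norm</sub> = I − D<sub>v</sub><sup>−1/2</sup> H W D<sub>e</sub><sup>−1</sup> H<sup>T</sup> D<sub>v</sub><sup>−1/2</sup>,

and the normalized association S = I − Δ<sub>norm</sub> is the Ho-FCN whose
strict upper triangle (length M(M−1)/2) is the subject's feature vector.

Features are z-scored per training fold, compressed by an L-layer tanh
encoder with linear decoder trained on reconstruction MSE (L = 3), and fed
to the BLS: n groups of random mapping nodes Z<sub>i</sub> = tanh(X W<sub>ei</sub> + β<sub>ei</sub>),
enhancement nodes H<sub>m</sub> = tanh(Z W<sub>hm</sub> + β<sub>hm</sub>), and a ridge
closed-form output weight W = (A<sup>T</sup>A + λI)<sup>−1</sup>A<sup>T</sup>Y
over A = [Z | H] with one-hot targets. Reported metrics are accuracy,
sensitivity, specificity and precision over repeats × folds.

## Worked example

```python
from hyperbroad import experiments as ex

results = ex.run_synthetic_cv(ex.signal_spec(seed=1), ex.experiment_config(seed=1))
print(results.summary())
```

```
Deep-broad brain-network classification — cross-validation summary
==================================================================
subjects: 120 (control: 60, positive: 60)
high-order features per subject: 780
folds: 10  repeats: 1  seed: 1
hypergraph k: 5  AE layers: 3  BLS nodes: 20x100+1x10
------------------------------------------------------------------
metric            mean %      sd %
accuracy            95.8       5.9
sensitivity         91.7      11.8
specificity        100.0       0.0
precision          100.0       0.0
```

The 120 synthetic subjects have 40 ROIs in 4 modules; the two classes
differ only in between-module coupling (0.1 vs 0.5). A mean accuracy near
96% says the hypergraph features retain that multi-region structure; on the
matched null dataset (no class difference) the same pipeline stays at
chance (~50%).

The same run from the shell:

```bash
hyperbroad generate data/demo --seed 1
hyperbroad run data/demo/manifest.csv --out results/demo
```

Other CLI verbs: `features` (dump per-subject Lo-FCN/Ho-FCN) and `metrics`
(recompute the metric table from saved predictions). Library users can
start from `DeepBroadModel.from_manifest(...)` / `.from_timeseries(...)`
and call `.fit()` for a `CvResults` object.

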