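# Methods

## Problem and model

`nirnet` classifies near-infrared (NIR) absorbance spectra by cultivation
region. The input is a vector of absorbance values on an equally spaced
wavenumber grid (by default 1609 points over 3800–10,000 cm⁻¹); the output
is one of C regions (by default 8, with a strongly imbalanced class
distribution). NIR spectra of plant material consist of broad, heavily
overlapping overtone/combination bands, so the discriminative signal is
diffuse and a deep 1-D convolutional network is a natural feature
extractor.

The reference architecture ("6C-3F") is:

```
BN(input) → [conv1d → BN → ReLU → maxpool(2, stride 2, ceil)] × 6
          → flatten → [FC → ReLU → dropout(0.5)] × 2 → FC(C) → softmax
```

* Convolutions are stride-1 with zero "same" padding, so only pooling
  changes length. The first three layers use width-9 kernels to capture
  broad band structure, the last three width-3 kernels for finer detail.
  Channel counts increase 32, 64, 96, 128, 192, 256 (the endpoints are
  fixed by design; the intermediate schedule is a package choice,
  configurable per layer).
* Ceil-mode pooling keeps a trailing partial window, so an input of
  length L has length `ceil(L/2)` applied k times after k pool layers;
  1609 → 805 → 403 → 202 → 101 → 51 → 26, giving a first
  fully connected layer of 26 × 256 = 6656 inputs.
* Batch normalization (ε = 1e-5, running-statistic momentum 0.9) is
  applied to the raw input and before every convolutional activation,
  each with its own learned scale/shift. Inference uses running
  statistics and is deterministic.
* Dropout is inverted (survivors scaled by 1/(1−p) at train time,
  identity at inference) and applies only after hidden FC activations,
  never to the output layer. Default p = 0.5.
* Weights are initialized MSRA/He — i.i.d. N(0, 2/fan_in), with
  fan_in = kernel_width × in_channels for convolutions and the input
  width for FC layers — when the activation is ReLU or leaky ReLU, and
  Xavier/Glorot — N(0, 2/(fan_in+fan_out)) — for sigmoid/tanh. A naive
  sd-0.01 Gaussian initializer is kept for the initialization ablation.

Training minimizes softmax cross-entropy plus an L2 penalty
λ·Σ‖W‖² over weight tensors (biases and BN parameters excluded,
default λ = 1e-4) by plain mini-batch SGD (batch 16; classical momentum
is available but off by default). The learning rate decays
exponentially, `lr(t) = 0.01 · 0.99^(t/1652)` with t the round (one
mini-batch update); the decay period 1652 is chosen so the schedule
passes through 2.42×10⁻⁵ at round 990,000, the documented endpoint of
the reference schedule whose period is otherwise unstated. A staircase
variant floors the exponent.

The whole network — convolution, BN, pooling, dropout, the backward
pass — is implemented directly on NumPy arrays with exact analytic
gradients. Convolution is computed as a sum of k shifted batched
matrix products so every inner product is a BLAS call. Arrays default
to float32 for throughput; dtype is a parameter, and the test suite
validates gradients against central finite differences in float64
(relative error ≤ 1e-4 through conv + BN + pooling + FC + softmax/CE +
L2).

## Evaluation metrics

Predictions are scored by a C×C confusion matrix (rows = given labels,
columns = predicted). Each class is binarized one-vs-rest into
(TP, FN, FP, TN) and scored by sensitivity TP/(TP+FN), specificity
TN/(TN+FP), precision TP/(TP+FP), and F1 = 2TP/(2TP+FP+FN) — the
harmonic mean of precision and sensitivity. Rates with zero denominator
are reported as undefined (None), never silently zero.
`reconstruct_counts` inverts printed sensitivity/precision (rounding
half-up) back to integer counts given the class size and evaluated
total; it is used to check published metric tables for internal
consistency, and the round trip counts → rates → counts is an exact
identity for totals ≤ 5000 (property-tested).

## Synthetic data generator

No public dataset with the reference study's structure exists, so the
generator emulates it: for a sample of class c on grid wavenumbers w,

```
a(w) = [ Σ shared bands + Σ class-c bands ] (w) · (1 + m)
       + b₀ + b₁·(w − w_mid) + ε(w)
```

with Gaussian band profiles, m ~ N(0, scatter_sd²) a per-spectrum
multiplicative scatter factor, b₀ + b₁·(w − w_mid) an additive linear
baseline, and ε i.i.d. N(0, noise_sd²) white noise. Labels are drawn
i.i.d. from the class proportions (a fixed-count mode apportions exact
counts by largest remainder for exact emulation of the reference
distribution).

The default ("tobacco-like") configuration: grid (3800, 10000, 1609);
8 classes with proportions 557 : 7668 : 1422 : 326 : 2897 : 132 : 164 :
204 (sum 13,370); four shared bands at typical C–H/O–H positions
(4300, 5180, 6900, 8400 cm⁻¹; widths 120–250 cm⁻¹; amplitudes
0.20–0.60 AU); two class-specific marker bands per class at distinct
centers (amplitudes 0.15 and 0.10 AU; widths 60 and 90 cm⁻¹);
noise_sd 0.005 AU, baseline offset sd 0.05 AU, baseline slope sd
1.5×10⁻⁵ AU/cm⁻¹, scatter sd 0.05. These magnitudes are typical of
bench FT-NIR absorbance data: band amplitudes an order of magnitude
above the noise floor, baseline/scatter variation comparable to band
amplitudes.

What the generator does *not* emulate: Beer–Lambert mixture chemistry,
instrument line shape, wavelength-correlated noise, within-class
chemical variability beyond global scatter/baseline, and between-class
overlap in band *positions* (class markers differ deterministically).
Synthetic classes are therefore more separable than real provenance
classes; passing the end-to-end tests demonstrates that the pipeline
learns, not that real-world accuracies transfer.

The stated resolution (8 cm⁻¹) and feature count (1609 points over
6200 cm⁻¹) of the reference data are mutually inconsistent; the feature
count wins and `n_points` is a free grid parameter.

## Baselines

* **SVM** — scikit-learn RBF-kernel SVC; `kernel_width` is the RBF σ
  (γ = 1/2σ²), defaulting to scikit-learn's `scale` heuristic.
* **GA-SVM** — a generational genetic algorithm over (log₂C, log₂γ, a
  bit mask over the top 50 principal components): tournament selection
  of size 2, single-point crossover on the mask with blending of the
  log hyperparameters, bit-flip/Gaussian mutation, elitism of 1.
  Fitness is stratified k-fold CV accuracy with PCA fitted on training
  folds only (no leakage). Elitism makes the best-fitness sequence
  non-decreasing.
* **ANN** — one sigmoid hidden layer (default width 64; the width is a
  package choice, the reference design states only "three layers")
  trained with the same SGD machinery as the CNN, Xavier-initialized,
  without BN or dropout.

All models share the fit/predict contract and are scored by the same
evaluation module.

## Experiment designs and problem sizes

The experiment module reproduces the study designs at desk scale:
layer sweep over {3..6} conv × {3,4} FC layers (tags like "6C-3F"),
activation comparison with the standard activation/initializer pairing,
a matched-seed MSRA-vs-naive-init ablation, and the four-model baseline
comparison. Budgets are deliberately small — the package's own choice
of problem size is n = 2000 synthetic samples (80/20 split) and
hundreds-to-thousands of training rounds, at which the default network
reliably exceeds 90% test accuracy on the default synthetic family
within a few hundred rounds. Absolute accuracies from the original
13,370-sample study are not targets at these sizes; the qualitative
orderings (deeper stacks not worse, ReLU+MSRA trainable where naive
init is slower, CNN ≫ shallow ANN on ample data) are what the designs
exercise. Every experiment writes a CSV plus a YAML config snapshot
sufficient to re-run it bit-identically.

## Numerical choices and degenerate inputs

* Softmax subtracts the row maximum before exponentiation (shift
  invariance is exact); cross-entropy clips the true-class probability
  at 1e-12; non-finite logits abort training with the failing round in
  the error message.
* BN in train mode requires batch size ≥ 2; a constant batch maps to
  zeros before the affine restoration (ε guards the division).
* Max pooling breaks ties toward the left element; a trailing orphan
  element passes through unchanged (ceil mode).
* Train/test splitting rounds the training size half-up; stratified
  mode applies the same rule per class.
* Class ids are 1-based everywhere in the public API.
* CSV I/O writes absorbances with 17 significant digits, so round trips
  are lossless to well below 1e-12.

## Known limitations

* CPU-only, single-threaded by design of the primitives; no GPU path.
* Stride-1 convolutions and width=stride pooling only in the training
  pipeline (the functional `max_pool` is general).
* The per-class "prediction accuracy" column of the reference study's
  metric table follows no recoverable definition (it matches neither
  sensitivity nor any binarization tried); the package reports
  (TP+TN)/total alongside sensitivity and does not attempt to
  reproduce that column.
* The GA-SVM is a faithful small-scale GA, not a tuned AutoML: with
  tiny populations/generations it can tie rather than beat a default
  SVM.
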