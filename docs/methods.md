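# Methods

## Model and assumptions

The classifier couples two ideas: rough neurons, whose paired
lower/upper weight sets give each hidden unit an interval-valued
response, and interval neutrosophic sets, which describe every
instance–class pair by three memberships (true T, indeterminacy I,
false F) in [0, 1] with T + I + F ≤ 3.

A rough hidden neuron computes two pre-activations `I_L = W_L·x`,
`I_U = W_U·x` (plus optional biases), passes both through the sigmoid
`f(x) = 1/(1+e^{−λx})`, assigns the smaller activation to the lower
output and the larger to the upper output, and emits their sum
`O ∈ [0, 2]`. The min/max assignment is per input: a neuron's branches
may swap between weight sets from one instance to the next. Input and
output layers are conventional; output scores are sigmoids, hence valid
memberships.

Two networks of identical architecture are trained independently on the
same rows: the true-membership network on one-hot class codewords, the
false-membership network on their bitwise complements. Indeterminacy is
defined as `I = 1 − |T − F|`: it is maximal when the two networks fail
to take opposite positions on a class, which is exactly the regime in
which a one-network score would look deceptively confident.

Decisions: `bit_c = [T_c > F_c]` per class (strict; an exact tie leaves
the bit 0 and defers to the fallback, which is appropriate since a tie
is maximal uncertainty). A codeword with one set bit names the class.
An all-zero codeword resolves to the class of maximum indeterminacy.
A codeword with several set bits resolves to the set bit with the
largest margin `T_c − F_c`, ties breaking to the earliest class in the
class order — the margin rule is this package's design choice for a
case the published material leaves open; it extends the binarization
criterion monotonically and is deterministic.

## Training

Plain stochastic backpropagation of `0.5·Σ(T − score)²`: per-sample
updates in a per-epoch shuffled order, no momentum, no regularization,
no validation-based early stopping. Training stops when the epoch mean
of `Σ(T − score)²` reaches `target_mse` or at `max_epochs`.

The gradient through the min/max routing is sent to whichever weight
set produced each branch in that forward pass, ties split 50/50.
Because the neuron emits the *sum* of the two branches, the routed
gradient is algebraically identical to the smooth gradient of
`f(I_L) + f(I_U)`; the finite-difference agreement tests therefore pass
at 1e-5 everywhere, including branch-swapping inputs.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `lambda_` | sigmoid steepness (dimensionless) | 1.0 | standard logistic |
| `gamma` | learning rate (dimensionless) | 0.1 | conservative for per-sample updates; tests use 0.5 on easy synthetic data |
| `tol_error` | Baum–Haussler tolerance Te | 0.1 | gives 7 hidden neurons at the benchmark's fold size (1701 training rows, 21 inputs, 3 outputs) |
| `max_epochs` | epoch cap | 1000 | generous; stopping usually triggers on `target_mse` |
| `target_mse` | stopping threshold on epoch MSE | 1e-3 | scores within ~0.03 of targets on average |
| `init_scale` | half-width of uniform weight init | 0.5 | keeps initial pre-activations in the sigmoid's responsive range for [0,1] inputs |
| `use_bias` | per-neuron bias | on | without biases sigmoid networks cannot shift decision boundaries |
| `hidden_sizes` | explicit widths | None | None ⇒ one hidden layer sized by Baum–Haussler at fit time |

None of these values are prescribed by the source material for the CTG
benchmark; they are this package's defaults and all are configurable.
The two networks' seeds derive from one master seed (seed and seed + 1)
so a dual model is a single reproducible object. Cross-validation
derives one sub-seed per fold from the master seed by a fixed affine
map, keeping every fold's training independent yet reproducible.

## Preprocessing and evaluation choices

- Min–max normalization to [0, 1], fitted on the training rows of each
  fold only and applied to test rows with clipping — a leakage-safe
  choice; constant columns map to 0.0 to avoid division by zero.
- NSP labels accepted as 1/2/3 or N/S/P, normalized to the order (N, S, P).
- Overall accuracy is the micro form 100·trace/total. The macro average
  of per-class one-vs-rest accuracies is exposed separately
  (`macro_ovr_accuracy`) because with k > 2 it credits every error to
  the k − 2 uninvolved classes and overstates performance (96.7% vs
  95.1% on the published 425-instance confusion matrix).
- Weighted precision/recall/F1 use actual-class supports as weights;
  support-weighted recall then equals micro accuracy by an algebraic
  identity that the tests assert. The harmonic-mean-of-weighted-means
  F1 variant is reported as a secondary field.
- One-vs-rest AUC uses the midrank statistic on the true-membership
  score T_c, which equals the trapezoidal area under the empirical ROC
  curve (cross-checked against scikit-learn in tests). Which score
  should feed the ROC is not fixed by the source material; T_c is this
  package's choice.
- A class never predicted (or absent) yields precision (recall) 0 with
  a warning, matching common tooling.
- Fold aggregation is the unweighted mean over folds.

## Synthetic data

The generator emulates the *shape* of the CTG problem, not its
physiology: `n_features` (default 21) class-conditional Gaussian
attributes, three classes with the benchmark's observed fold imbalance
342:52:31 by default, exact counts by largest-remainder rounding.
Class centers sit at pairwise distance `separation` (in units of the
within-class spread `noise_sd`) along random orthogonal directions;
`separation = 0` is a pure null model, `generate_separable` uses 6
spread units, far enough that a nearest-centroid oracle is near-perfect.
The matrix is min–max scaled to [0, 1] columnwise.

What passing tests on this data do show: the optimizer descends, the
dual-network memberships anti-correlate where they should, accuracy
responds monotonically to separability, and the full pipeline is
deterministic under a seed. What they do not show: performance on real
CTG recordings, whose attributes are skewed, heavy-tailed, discrete in
places and correlated — none of which the Gaussian generator imitates.

## Problem sizes used by the test suite

Convergence and cross-validation checks run on 300-instance separable
or null datasets with a 100-epoch budget (γ = 0.5, `target_mse` 5e-3),
and the separation-monotonicity sweep uses 150 instances, 3 folds,
30 epochs over three seeds; these sizes are the package's choice of a
compact yet discriminating regime for three-cluster Gaussian data.
Worked-example fixtures (the published membership tables and confusion
matrix) are exact and independent of any training.

## Known limitations

- The published headline CTG results depend on the original UCI export
  and on hyperparameters that were never printed; they cannot be
  reproduced from the package alone, and the fixtures instead pin every
  printed worked example exactly.
- The multi-set-bit resolution rule has no published worked example to
  verify against (see above); it is tested for totality, determinism
  and consistency with the binarization criterion only.
- Memberships are raw network outputs, not calibrated probabilities.
- No momentum, adaptive optimizers, regularization or feature
  selection; the training loop is deliberately the plain delta rule.
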