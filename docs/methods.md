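# Methods

This note records the scientific and numerical choices behind `quanvkd`: what
the hybrid model is, what the synthetic data does and does not emulate, and
where the design was genuinely open.

## The hybrid model

The pipeline classifies grayscale images by severity grade in four stages.

**Deterministic front end.** Images are converted to grayscale (channel
average), bilinearly resized to `target_side` (default 28), and a centered
`roi_side` x `roi_side` region of interest (default 14) is cropped with
0-based, half-open coordinates and floored margins. Two views are derived:
the ROI clipped to [0, 1] feeds the quantum stage, and the standardized
full image X' = (X - mu) / max(sigma, eps) — dataset-level mean and standard
deviation, eps = 1e-8 guarding constant images — feeds the classical teacher.
Keeping the quantum view on the raw [0, 1] scale ensures the angle encoding
below is a bijection.

**Quanvolution.** The ROI is tiled into non-overlapping 2x2 patches. Each
patch is reduced to two scalars — by default the two row means, so all four
pixels contribute; a `first_two` mode selects the top row instead — and the
scalars v are encoded as RY rotation angles pi * v on a 2-qubit register
(scale pi rather than 2*pi so distinct inputs map to distinct states). A
parameterized entangling block follows: per layer, an RY on every qubit and
then a CNOT chain (one CNOT for 2 qubits), with angles drawn uniformly on
[0, 2*pi) from a seed. Both qubits' Pauli-Z expectations are measured;
patch (i, j) contributes the two channels at map position (i, j). A 14x14
ROI therefore yields a 7x7x2 feature map with every entry in [-1, 1].

The simulator is a dense statevector implementation (qubit 0 = most
significant basis bit). Because the entangling block is fixed within a run,
its gates are collapsed into a single 4x4 unitary (built by applying the
simulator to basis states) and a whole dataset is quanvolved as one batched
matrix product; tests verify this fast path against the per-patch circuit
and an independent Kronecker-product matrix oracle.

**Frozen vs trainable block.** The entangling block is frozen by default, so
feature maps are precomputed once and cached (archives embed a hash of the
block parameters and geometry; a mismatching cache raises rather than being
silently reused). In trainable mode caching is refused and exact gradients
of every map entry with respect to every angle are available through the
parameter-shift rule, d<Z>/d(theta) = [f(theta + pi/2) - f(theta - pi/2)]/2.
Quanvolution practice freezes the random layers, and the frozen default is
what the end-to-end pipeline uses; the gradient machinery makes the joint
mode usable without being the default path.

**Classifiers.** Both CNNs share one topology: Conv(3x3, same) -> ReLU ->
MaxPool(2x2, skipped if a spatial side is below 2) -> Conv(3x3, same) ->
ReLU -> Flatten -> Dense(64) -> ReLU -> Dropout(0.5) -> Dense(K) logits;
softmax is applied only at the loss/inference level. The teacher uses
(128, 256) filters on standardized images; the student uses (64, 128) on
the quantum feature maps. On a 7x7 input only one 2x2 pool fits before
spatial collapse, hence pooling after the first convolution only. Weights
are Glorot-uniform from a run-level seed. The networks and the training
loop (Adam, lr 1e-3, batch 8, up to 100 epochs) are implemented directly
in numpy with hand-written backprop; finite-difference tests pin the
gradients of every layer and of the composed losses.

**Knowledge distillation.** The trained teacher is frozen (enforced by a
weight checksum before/after) and its logits over the training set are
computed once. The student minimizes

    alpha * CE(y, softmax(S)) + (1 - alpha) * KL(softmax(T/temp) || softmax(S/temp))

with temperature 5 and alpha 0.5 by default. The KL direction is
teacher-as-reference, the standard convention; the classical T^2 rescaling
of the soft term is available behind `squared_t_scaling` but off by default,
matching the loss as configured above. Gradients are analytic:
alpha*(p - y) + (1 - alpha)*(soft_S - soft_T)/temp per logit.

**Evaluation.** Stratified 80/20 hold-out repeated (ten repeats by default;
repeat r uses seed base+r), confusion matrix, per-class precision/recall/F1,
macro and support-weighted averages (weighted recall equals accuracy by
construction), and one-vs-rest AUC by the Mann-Whitney rank statistic with
midrank tie handling — exact and tie-safe, unlike trapezoid-on-thresholds.
Zero denominators yield 0 with a warning. All metrics are computed from
counts in this package and cross-checked against scikit-learn in tests.
Aggregation across repeats reports mean and population standard deviation
(one repeat gives sd 0).

## The phantom generator

Real graded dementia MRI is out of scope; the synthetic "atrophy phantoms"
provide a desk-scale stand-in with the same statistical shape. Class k of K
is a centered, mildly elliptical (axis ratio 0.88) bright ring around a dark
cavity on a faint disc; cavity radius and ring thickness grow monotonically
with k, a ventricle-enlargement proxy that makes class confusions ordinal
and interpretable. Defaults: 28x28 canvas (the quanvolution reads only the
14x14 center, so larger canvases waste compute; the side is configurable),
additive Gaussian noise of sd 0.05 clipped to [0, 1] — mild, pixel-level
noise that leaves a nearest-centroid baseline clearly above chance, which
the test suite asserts as the guarantee that downstream learners have
signal. Class proportions default to 0.14 / 0.01 / 0.50 / 0.35, the
imbalance of the 6400-slice 4-class collection the phantoms emulate
(896 / 64 / 3200 / 2240 at n = 6400); proportion rounding floors and the
remainder goes to the largest class.

Augmentation draws rotation (+-15 degrees), horizontal flip (p = 0.5), zoom
(+-10%) and shift (+-10% of the side) uniformly within limits — standard
mild magnitudes, since none are pinned down externally — and `rebalance`
tops deficit classes up with augmented copies of their own members while
subsampling surplus classes without replacement. The post-augmentation
class targets are exposed as explicit `target_counts` rather than a
hard-coded multiplier scheme.

What the phantoms do **not** emulate: MRI physics, anatomy, intensity
inhomogeneity, inter-subject variability, or the visual similarity between
adjacent clinical grades. Accuracies near 1.0 on phantoms demonstrate that
the pipeline is wired correctly and can learn an ordinal structural signal
through the quantum features — not that comparable accuracy would be reached
on clinical data.

## Problem sizes and determinism

The package's own benchmark runs are desk-scale: the end-to-end learning
check uses 1600 phantoms rebalanced to 400 per class with the student
trained up to 20 epochs, and the two-arm comparison and the acceptance
script use 600 phantoms rebalanced to 150 per class with up to 8 epochs —
sizes at which the full experiment, teacher included, completes in minutes
on one CPU while leaving the learning problem non-trivial. Runs are
deterministic: every stage's randomness derives from the run seed by fixed
offsets (data, rebalancing, per-repeat splits, weight init, batch shuffling,
dropout), and repeating a configuration reproduces the summary CSVs
bit-identically in single-threaded execution.

A validation subset (10% of the training split, stratified, seeded) is
carved out for early stopping, which monitors validation cross-entropy with
patience 10 and restores the best weights; the held-out test split is never
used for stopping.

## Numerical choices

- Statevector norm is asserted to 1e-8 on construction; gates are exactly
  unitary up to float rounding (tested at 1e-10).
- Softmax is max-shifted; cross-entropy and KL clip probabilities at 1e-12,
  so a zero probability yields a large finite loss rather than an overflow.
- Max-pool gradients are split equally among tied maxima, keeping the
  backward pass deterministic.
- Angle-encoding inputs outside [0, 1] are clipped with a warning rather
  than rejected (resampling can produce values epsilon outside the range).
- The teacher's input modality is an open choice; the default gives the
  teacher standardized images (highest-capacity view) and the student the
  quantum maps, with `teacher_on_quantum_features` switching the teacher to
  the quantum view.

## Known limitations

- The simulator is dense and targets small registers (the pipeline uses 2
  qubits); it has no mixed states, noise channels, or shot sampling.
- Trainable-block gradients are exposed but the orchestrated pipeline does
  not jointly optimize circuit angles with CNN weights.
- Only the Adam optimizer is provided.
- The distillation comparison on phantoms is reported without asserting
  which arm must win: on data this separable both arms saturate, and
  externally the direction of the KD effect is itself equivocal.
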