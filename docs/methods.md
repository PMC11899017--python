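# Methods

## The search problem

The package automates CNN macro-architecture design for multiclass image
classification.  A candidate architecture is a sequence of *macro slots*:
each slot contributes either a standard convolution (filter size FS ∈ [2, 8],
filter count NF ∈ [8, 512], stride S ∈ [1, 3]) or a multi-branch block
(NB ∈ [2, 4] parallel convolutions with kernels 1, 3, 5, 7 — branch *i* uses
kernel 2i−1 — each with NF ∈ [4, 128] filters, stride 1, concatenated
channel-wise), optionally followed by a max/average pooling layer
(FS ∈ [1, 7], S ∈ [1, 3]).  Optional fully connected layers (NN ∈ [10, 512])
may precede the fixed classifier head: global average pooling, a dense layer
to the K classes, softmax.  All bounds are user-overridable.

### Encoding

The genome is a vector in [0, 1]^D with one contiguous gene group per slot:
`{conv_control, conv_FS, conv_NF, conv_S, mb_NB, mb_FS, mb_NF}` then
`{pool_control, pool_type, pool_FS, pool_S}` per macro slot, and
`{fc_control, fc_NN}` per FC slot (D = 11·M + 2·F).  Control genes choose
the conv variant and gate pooling/FC presence; genes of the unselected
variant travel silently with the particle, keeping D fixed for the swarm.
Decoding uses V = round(L + (U − L)·P), rounding half away from zero; the
inverse map (V − L)/(U − L) round-trips exactly for every integer in every
range, which is how the published reference model is reconstructed from its
printed hyperparameters.  The multi-branch FS gene is decoded but unused —
branch kernels are fixed by branch position, the only pattern consistent
with the reference model's layer table — and its value is logged in the
decode provenance.

### Shape rules, repair, feasibility

Convolutions use SAME padding (out = ceil(in/S)); pooling uses VALID
(out = floor((in − FS)/S) + 1).  These conventions are the pair that
reproduces the reference model's printed activation extents (224 → 110 → 55
→ 26 → 12 → 6 → 2).  A pooling layer whose filter exceeds the current
spatial extent is infeasible; `repair` removes such layers front-to-back and
re-propagates, always terminating (convolutions cannot drive an extent below
1 under SAME padding), and is idempotent.  Hardware suitability is modelled
by two budgets — total learnable parameters and peak per-sample activation
cells (defaults 10 M and 50 M) — a deliberately hardware-independent proxy
for a GPU-memory limit; over-budget candidates get worst-case fitness 1.0
without training.

### Swarm dynamics

Global-best PSO with velocity clamp 0.2 (20 % of the unit range), inertia
linearly decayed 0.9 → 0.4 over the run, c₁ = c₂ = 1.49445 — widely used,
stable defaults, adopted because the source protocol does not state its
coefficients; all are configurable.  r₁, r₂ are scalar per particle per
iteration (a per-coordinate variant is available behind
`per_coordinate_r=True`).  Positions are clipped to [0, 1] after each move
and the velocity of a clipped coordinate is zeroed, preserving the decode
precondition without rejection sampling.  Fitness is minimised; equal
fitness keeps the earlier incumbent, making runs deterministic under a
fixed seed.  The global-best history is nonincreasing by construction.

### Fitness and the two-stage protocol

Fitness of a genome is L = 1 − accuracy of the decoded, repaired,
budget-checked, trained candidate.  Training follows the fixed protocol:
SGD with momentum 0.9 (the mainstream framework default; the source
protocol leaves it unstated), initial learning rate 1e-4, piecewise
schedule multiplying by 0.8 every 5 epochs ("reduced by 20 %" read
multiplicatively — the only reading that applies repeatedly), batch 32,
L2 1e-4 on weights only, validation recorded every 50 iterations.  Stage 1
screens candidates for a few epochs on a class-balanced subsample (default
200 per class); stage 2 retrains the best architecture at full length on
the full training split and produces the final report.

The fitness split defaults to the **test** split, faithfully mirroring the
protocol this package reimplements; that choice leaks test data into the
search, so `fitness_split="validation"` is provided and recommended for new
studies.  No early stopping is implemented; the validation frequency only
controls curve recording.

### Metrics

From the confusion matrix (rows = true, columns = predicted):
one-vs-rest per class, precision TP/(TP+FP), recall TP/(TP+FN), specificity
TN/(TN+FP), F1 = 2TP/(2TP+FP+FN), per-class accuracy (TP+TN)/N (the
one-vs-rest definition); unweighted macro averages; overall accuracy
trace/N.  Degenerate denominators yield 0 with a flag.  ROC-AUC is computed
per class one-vs-rest from the midrank (Mann–Whitney) statistic, equivalent
to the trapezoidal ROC integral with tied scores handled by midranks.
Cohen's κ = (p₀ − pₑ)/(1 − pₑ); κ = 0 with a warning when pₑ = 1.  All of
these are hand-computed from counts and cross-checked against
scikit-learn's implementations in the test suite.

## Training backend

Training runs on a purpose-built numpy engine: im2col-lowered SAME-padded
convolutions, VALID pooling, ReLU after every convolution and hidden dense
layer, no normalization layers (the reference model's parameter counts
match bias-carrying convolutions with no batch-norm parameters), float32
throughout, reverse-mode gradients verified against central differences.
Being pure numpy it is deterministic to the bit for a fixed seed — the
strict-determinism property the search and the tests rely on — and its
`num_parameters()` (a direct enumeration of allocated learnable arrays) is
the independent oracle for the analytic parameter accounting.

## Class balancing

The balance plan raises every class to the majority-class count
(additions(c) = max(counts) − counts(c)).  The oversampler seat is
pluggable: the default `transform-oversample` strategy appends
label-preserving transforms of class originals (flips, 90° rotations, small
shifts, intensity jitter); any conditional generator — e.g. a trained
conditional GAN — can be plugged in as a callable `(class_label, rng) →
image`.  Appended images carry a `synthetic` provenance flag; originals are
never modified.  Balancing defaults to after the split (training split
only) because balancing first leaks augmented kin of one image across
splits; `balance_before_split=True` reproduces the balance-first ordering.

## Synthetic benchmark data

`generate_synthetic` emulates a class-conditional image corpus: class k's
images are a shared background plus a class-keyed pattern (Gaussian blob
position on a circle, sinusoidal texture frequency/orientation, colour
tilt) scaled by `separability`, plus Gaussian pixel noise (default σ = 10
on the 0–255 scale).  At separability 1.0 a small CNN reaches ≥ 0.9 test
accuracy; as separability → 0 all classes collapse onto the background and
accuracy falls to 1/K (both calibrations are asserted in the tests).  What
it does *not* emulate: the intra-class variability, acquisition artefacts,
colour constancy problems and label noise of real dermoscopy images — so
passing desk-scale searches demonstrate the pipeline's correctness and
optimizer behaviour, not clinical-grade performance.

## Problem sizes and the desk-scale preset

Full-scale runs (224×224 images, NF up to 512, tens of thousands of
gradient steps) belong on a GPU.  The package's experiments and tests use
the `SearchSpace.small()` preset — 3 macro slots, conv NF ∈ [8, 32],
multi-branch NF ∈ [4, 16], FS ∈ [2, 5], NN ∈ [10, 64] — on 16×16 synthetic
images with a swarm of 4 over 6 iterations, 3-epoch screening and 10-epoch
final training.  At this scale trainings are ~100 gradient steps, so the
desk-scale runs use initial learning rate 1e-2: the production rate of 1e-4
is sized for ~70 k-step GPU runs and moves nothing in 100 steps.  The
protocol's schedule shape, momentum, batch size and L2 are unchanged.  The
`TrainConfig` default remains 1e-4 (the reference protocol).

## Numerical notes and known limitations

- Rounding in denormalization is half-away-from-zero; with the default
  nonnegative bounds this equals floor(x + 0.5).
- The FLOP counter uses 2·FS²·Cin·NF·Hout·Wout per convolution and 2·Cin·Cout
  per dense layer, pooling and activations zero.  Published FLOP figures
  follow varied conventions (multiply-accumulate vs separate, auxiliary ops
  included or not); totals here are comparable only within this convention,
  which the output metadata states.
- The reference model's first pooling layer is reconstructed with FS 6
  (VALID, stride 2: 224 → 110); its printed 1×1 filter cannot produce that
  extent under any standard convention and pooling filters carry no
  parameters either way.
- The reference model's printed total "4.4 M" is the rounded column sum;
  the exact sum 4,465,082 is what the accounting reproduces.
- An architecture reduced by repair to the classifier head alone is valid
  and trainable (it degenerates to logistic regression on channel means).
- Skip/residual connections, attention, depthwise convolutions and
  non-integer hyperparameters are outside the search space by design.
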