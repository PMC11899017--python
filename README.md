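# sadasnet

Particle-swarm neural-architecture search for selective/adaptive CNNs,
built for multiclass dermoscopy image classification (the seven HAM10000
lesion classes: akiec, bcc, bkl, df, mel, nv, vasc) but usable on any
image-folder + label-CSV dataset or on its own synthetic benchmark data.

## What it does

Candidate CNN macro-architectures are encoded as fixed-length vectors
**P ∈ [0, 1]^D** (particle positions).  Each gene maps to one integer
hyperparameter through the bounded denormalization rule

    V = round(L + (U − L) · P)

with per-gene bounds such as filter size FS ∈ [2, 8], filter count
NF ∈ [8, 512], branch count NB ∈ [2, 4] and neuron count NN ∈ [10, 512].
Control genes select between a standard convolution and an inception-style
multi-branch block (parallel 1×1/3×3/5×5/7×7 convolutions, channel-wise
concatenation), and gate optional pooling and fully connected layers.  A
global-average-pooling → dense → softmax classifier head is always appended.

The swarm minimises the loss **L = 1 − accuracy** of each trained candidate
with the standard velocity/position updates

    vᵢ ← ω vᵢ + c₁ r₁ (pbestᵢ − xᵢ) + c₂ r₂ (gbest − xᵢ),   xᵢ ← xᵢ + vᵢ

under a two-stage protocol: a cheap few-epoch screening on a per-class
subsample during the search, then a long final training of the winner.
Architectures whose pooling layers outgrow the feature map are repaired by
layer removal; candidates breaking the parameter/activation budget receive
worst-case fitness.  The final model is reported with a confusion matrix,
one-vs-rest precision/recall/specificity/F1/accuracy, ROC-AUC and Cohen's κ.

Training runs on a self-contained numpy CNN engine (im2col convolutions,
SGD with momentum, the piecewise learning-rate schedule), so results are
bit-reproducible for a fixed seed on any CPU.

## Worked example

Search on the built-in synthetic benchmark (4 classes, 16×16 images,
100 per class, desk-scale search space):

```
$ sadasnet search --seed 1 --out runs
run CNN16_4_6: best fitness 0.0000, test accuracy 1.0000, kappa 1.0000
artifacts in runs/CNN16_4_6
```

The run directory is named `CNN{image_size}_{population}_{iterations}` and
contains the config snapshot, the best architecture JSON, the per-iteration
convergence CSV, the evaluation report JSON, the confusion-matrix CSV,
per-class ROC CSVs and the log.  `best fitness` is the stage-1 screening
loss 1 − accuracy of the best particle (0 means the screened candidate
classified the fitness split perfectly); `test accuracy` and `kappa` come
from the stage-2 final training.

Inspect the published 224×224 reference model that ships with the package:

```
$ python -c "from sadasnet.reference import reference_architecture
from sadasnet.architecture import serialize
open('ref.json','w').write(serialize(reference_architecture()))"
$ sadasnet describe ref.json
layer                       activations    filters  kernel  stride      params         flops
--------------------------------------------------------------------------------------------
multibranch_0_branch_1      224 x 224           87       1       1         348    26,191,872
multibranch_0_branch_2      224 x 224           87       3       1       2,436   235,726,848
multibranch_0_branch_3      224 x 224           87       5       1       6,612   654,796,800
pool_1                      110 x 110          261       6       2           0             0
conv_2                      55 x 55            112       6       2   1,052,464 6,366,729,600
...
classifier                  1 x 1                7       1       1         595         1,176
--------------------------------------------------------------------------------------------
total                                                                4,465,082 8,735,749,752
```

Per-layer parameter counts reproduce the published layer table of the
reference model exactly (total 4,465,082 learnable values).  FLOP totals are
convention-dependent — this counter uses 2·FS²·Cin·NF·Hout·Wout per
convolution (multiply + add) and says so in its output metadata — so they
are comparable across models counted the same way, not across publications.

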