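# Methods

## Problem and model

White-matter hyperintensities (WMH) related to focal cerebral ischemia (FCI)
and lacunar infarction (LACI) appear as tiny bright blobs on T2 FLAIR MRI
slices. The two classes are indistinguishable on T2; they separate on the
co-registered T1 FLAIR slice, where a LACI is dark and an FCI is isointense
with surrounding tissue. `lesioncorrect` implements the corresponding
two-stage *segmentation-correction* cascade:

1. **Primary network** — a U-Net-style encoder-decoder maps the T2 slice to
   per-pixel class probabilities. At depth *d* the encoder has 2·*d* 3×3
   convolutions (10 at the default depth 5), each followed by batch
   normalization and ReLU, with 2×2 max-pooling between levels and channel
   widths doubling per level. The decoder mirrors this with 2×2 transposed
   convolutions that halve the channel count, skip concatenations, and double
   convolution blocks; the head is two 1×1 convolutions followed by a
   per-pixel softmax. Convolutions use "same" padding: the skip
   concatenations and the equal input/output size are only consistent with
   size-preserving convolutions. In *task b* the network predicts
   background/lesion (2 classes); in *task a* it predicts
   background/FCI/LACI (3 classes) in a single stage.
2. **Instance extraction** — connected components of the binary
   (argmax > background) mask, 8-connected by default (lesions are blob-like;
   diagonal pixels belong together). Softmax ties resolve to background.
3. **Secondary network** — for each component, a 32×32 T1 window centred on
   the component centroid is upsampled to 64×64, min-max normalized, and
   gamma-transformed (out = in^γ, γ = 1.5, compressing dark intensities
   relative to bright ones). A five-convolution CNN with three 2×2 poolings
   (average by default) scores the patch with a single sigmoid probability
   P(LACI). Two heads are provided because the architecture admits both
   readings: two 1×1 convolutions followed by global average pooling
   (default) or two fully connected layers; either uses dropout (rate 0.5)
   during training only. A score strictly above 0.5 relabels the instance
   LACI, otherwise FCI (deterministic tie-break to the reversible-lesion
   class).
4. **Correction** — each instance's pixels receive its predicted class. The
   correction only relabels: the binary foreground is preserved bit-exactly.

Both networks are implemented as compact NumPy layers with explicit
backpropagation (float32, im2col convolutions); the optimizer is RMSProp,

    E[g²]_t = α·E[g²]_{t−1} + (1−α)·g²_t
    W_{t+1} = W_t − η/√(E[g²]_t + ε) ⊙ g_t

with α = 0.9, base learning rate η = 0.01, ε = 1e−8, applied per weight
using the *updated* accumulator. `training.rmsprop_update` is a pure
function and is tested against an independent scalar recurrence.

## Training strategies for tiny lesions

Lesion pixels are ≪ 1 % of a slice, so plain cross-entropy training
collapses to the all-background solution. Three remedies are implemented:

- **Oversampling (two-phase schedule).** Slices with more than 5 lesions are
  used alone for phase-1 pre-training until convergence (no loss improvement
  > 1e−4 for `convergence_patience` = 5 epochs, an operationalization chosen
  here since no criterion is inherent to the schedule), then phase 2
  continues on all training slices. When phase 1 and phase 2 use identical
  slices the loop is provably identical to single-phase training with summed
  epochs, which is tested.
- **Rotation augmentation.** Lesion-rich slices (> 5 lesions) get rotated
  copies at angles drawn from ±[5°, 10°]; images rotate bilinearly, masks by
  nearest neighbour so labels stay in {0, 1, 2}. Augmentation is applied
  inside each cross-validation training fold only — augmenting before the
  split would leak rotated copies of test slices into training.
- **Class weighting.** Optional per-class weights in the segmentation loss
  (default: none). At desk scale (tens of slices, tens of epochs, one CPU)
  weighting is what brings convergence inside the epoch budget; the phantom
  benchmark uses weight 8 on lesion classes together with the oversampling
  schedule.

Secondary-network training uses ROIs extracted at *ground-truth* component
centroids with their true class labels (a predicted-centroid mode exists);
binary cross-entropy on P(LACI). On small ROI sets the classifier trains
more stably at η = 0.003 with 20 epochs, which the benchmark uses; the
benchmark also selects the fully connected head, because the ROI's
discriminative evidence sits at the patch centre and global average
pooling in the convolutional head dilutes it 1:64, which makes that head's
training unreliable at this data scale.

Two further stabilizations apply at desk scale. First, after training, the
batch-normalization running statistics are **recalibrated**: one pass over
the training set in batch-statistics mode (dropout off) replaces the
running mean/variance with population estimates. Running averages kept
during optimization lag the final weights, and that mismatch can make
evaluation-mode outputs inconsistent with what the network learned.
Second, `train_primary` accepts a phase-2 learning-rate decay
(multiplicative per epoch; default off): constant-rate RMSProp never
anneals, so late epochs can walk out of a good minimum; decaying the rate
lets them fine-tune instead.

## Phantom generator

No clinical data accompany the package, so `phantom` generates paired
T2/T1 slices with exact ground truth: an elliptical "brain" at intensity
0.40 over a 0.05 background, lesions planted as non-overlapping disks of
radius 1–4 px, painted 0.90 on T2 for both classes, and on T1 0.40 (FCI,
isointense) or 0.10 (LACI, dark); i.i.d. Gaussian noise (default sd 0.02)
is added and intensities clipped to [0, 1]. Lesion counts per diseased
slice are uniform on 1–12 (the augmentation/oversampling threshold of 5
falls mid-range, so both phases are exercised). Patients are healthy with
probability 37/113 and, if diseased, LACI patients with probability 30/98,
mirroring the clinical cohort proportions; FCI patients carry only FCI
lesions while a LACI patient's lesions are LACI with probability 0.7
(mixed pathology occurs clinically). For small benchmark cohorts the types
can instead be fixed by quota so that every CV fold contains both classes.

What the phantom does *not* emulate: irregular lesion shapes, Rician noise,
bias fields, partial-volume boundaries, inter-modality registration error,
anatomy other than a uniform brain ellipse. Passing benchmarks on the
phantom therefore demonstrates that the cascade's machinery — training
schedules, instance extraction, ROI classification, correction, metrics —
works end to end on separable data; it says nothing about accuracy on
clinical scans.

## Evaluation protocol

Segmentation is scored by the Dice coefficient (pooled over a fold's
slices), detection and classification by precision. A predicted instance is
a true positive only if its pixel-set IoU with a ground-truth instance is
*strictly* greater than 0.6 (bounding-box IoU is available); matching is
greedy one-to-one in descending IoU order, which equals the exhaustive
optimal assignment at the instance counts that occur here (tested against
an oracle). Classification precision is the fraction of matched instances
with the correct class. Cross-validation is five-fold at the patient level
(slice-level splitting available), with seeded reproducible folds; every
slice is tested exactly once. Folds where a precision is undefined (no
predicted positives) are excluded from the fold mean rather than counted
as zero.

## Benchmark conditions

`benchmark.run_phantom_benchmark(seed)` fixes the study conditions used by
the acceptance script and the end-to-end tests: 20 patients × 3 slices at
128×128 (7 healthy / 8 FCI / 5 LACI by quota), primary U-Net preset depth 3
with base width 4, secondary CNN base width 8 with the fc head, primary
training 6 + 12 epochs at batch size 4 with lesion weight 8 and phase-2
rate decay 0.9, secondary 20 epochs at batch 16 and η = 0.003. These sizes
keep a full four-variant, five-fold run in minutes on one CPU while
leaving the task separable; batch size 4 was chosen because the additional
optimizer steps per epoch make fold-level convergence robust to
initialization. All randomness (phantom, folds, initialization, batch
order, dropout) derives from the single seed.

## Numerical and design choices

- Centroids are real-valued means of component pixel coordinates, rounded
  half-away-from-zero only when the ROI window is placed.
- ROI order of operations: crop → upsample → normalize → gamma, so the
  power transform acts on [0, 1] as intended. Constant patches normalize to
  all zeros by convention. Crops exiting the image zero-pad.
- Rotation angles outside ±[5°, 10°] are rejected as a precondition.
- `dice(both empty) = 1.0`; `precision(0/0)` is undefined (NaN), never 0.
- Argmax ties → background; classifier score exactly at threshold → FCI.
- The RMSProp step guards division by ε inside the square root, exactly as
  specified; gradients are validated finite, shapes strict.
- Batch normalization keeps running statistics with momentum 0.9 for
  evaluation mode; dropout and batch statistics are training-only, so
  inference is deterministic given fixed weights.

## Known limitations

- The NumPy networks are CPU-bound; the presets are intentionally small,
  and the full-size default specs (depth 5, base 64) build and run but are
  not practical to train here.
- Disk-shaped phantom lesions make IoU > 0.6 matching nearly binary
  (predictions are either near-perfect or absent); real lesion boundaries
  would make the threshold bite harder.
- The one-stage task-a baseline classifies from T2 alone, where the classes
  carry no signal by construction (as in the clinical contrast semantics);
  its classification precision therefore approximates the majority-class
  rate, which is the intended contrast with the T1-informed second stage.
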