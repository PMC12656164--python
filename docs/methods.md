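# Methods

## The problem

Wearable-sensor human activity recognition (HAR) models are trained on
windows of multichannel inertial signals (accelerometer, gyroscope) labeled
with an activity class. Deployed models meet *people who were not in the
training set*, and sensor signals vary strongly across individuals — body
shape, gait, sensor placement — so a classifier that is excellent on
held-out *windows* of its training users can degrade sharply on held-out
*users*. This package implements a single-stage multi-task remedy: train
the activity classifier jointly with a supervised contrastive objective
whose positive/negative structure is built from both activity and user
labels, so the encoder is pushed toward activity-discriminative,
user-invariant representations.

## Model

Three networks share one encoder:

* **Encoder F_θ** — a 1-D time-series ResNet: three residual blocks of
  three same-padded stride-1 convolutions (kernels 8/5/3; filters
  64/128/128 at full size) with batch norm and ReLU, an identity shortcut
  (1×1 projection + batch norm when channel counts change) added before the
  block's final ReLU, then global average pooling over time. The feature
  dimension equals the last filter count and is independent of window
  length. At full size the encoder has ≈0.5 M parameters.
* **Projection head H_φ′** — one hidden ReLU/dropout layer, then a linear
  map, then ℓ2 normalization: z = H(f)/‖H(f)‖. Used only in training.
* **Classification head G_φ** — three fully connected layers (ReLU +
  dropout on the two hidden ones) ending in C activity logits.

Each training step samples a batch of B windows. The raw windows pass
through encoder + classifier and yield the cross-entropy L_CE. Two
independently augmented views of the same windows (jitter always; scaling,
channel shuffle, sign flips, segment permutation each with probability p)
pass through encoder + projector and yield the supervised contrastive loss
on the stacked 2B embeddings:

    L_CL = mean over valid anchors i of
           −1/|P(i)| Σ_{p∈P(i)} log [ exp(z_i·z_p/τ) / Σ_{a∈A(i)} exp(z_i·z_a/τ) ]

with the total objective L = L_CE + λ·L_CL. The two branches share encoder
weights but run as separate forwards, so each normalizes with its own batch
statistics — the classification branch's batch norm is never polluted by
sign-flipped, rescaled or channel-shuffled views (stacking all 3B rows into
one forward measurably depresses unseen-user macro-F1). The raw branch runs
second, so the running statistics used at inference lean toward
un-augmented inputs. Gradients route structurally: the encoder receives
∂L_CE + λ∂L_CL, the classifier ∂L_CE only, the projector λ∂L_CL only; the
optimizer (AdamW) steps only the components the step's objective involves,
so a λ=0 run leaves the projector bitwise at its initialization. Inference
uses raw windows through encoder + classifier only.

### Pair strategies

* `instance` — the only positive is the sibling augmented view; every
  other row is a denominator candidate (the NT-Xent / SimCLR convention).
* `activity` — positives are all rows with the same activity label; all
  off-diagonal rows are candidates (standard supervised contrastive).
* `activity_user_hard` — positives are same-activity rows from a
  *different* user; hard negatives are same-user rows with a *different*
  activity; the denominator set A(i) is restricted to positives ∪ hard
  negatives. This is the user-aware strategy the package exists for. Two
  flags relax it back to the standard convention: `strict_positives=False`
  re-admits same-user positives (including the sibling view), and
  `restrict_denominator=False` widens A(i) to all off-diagonal rows.

Anchors with an empty positive set are skipped — the loss is undefined
there — and the reduction is the mean over valid anchors so λ stays
comparable across batch sizes (a `reduction="sum"` flag recovers the
plainly summed form). A stratified batch sampler pairs same-activity
windows across different users before chunking into batches, which keeps
empty-anchor batches rare. Log-sum-exps are stabilized by per-anchor max
subtraction.

### Training modes

* `multi_task` — the single-stage joint objective above, with early
  stopping on validation macro-F1 (the primary metric) and best-validation
  weights restored at exit.
* `supervised_only` — λ=0: cross-entropy alone (the baseline).
* `two_stage` — the protocol the single-stage method replaces: contrastive
  pretraining alone (encoder + projector) for `pretrain_epochs`, then the
  encoder is frozen and the classifier is fit on cached features with
  cross-entropy. With the `instance` strategy this is SimCLR pretraining +
  linear-ish probing; with the label strategies it is two-stage SupCon.

## Autodiff backend

The networks, losses and optimizer are implemented on numpy with
reverse-mode autodiff (`autograd`). The two hot operations carry
hand-written adjoints registered as autograd primitives: the same-padded
1-D convolution (sliding-window view contracted by einsum, with the
transposed-and-flipped correlation as the input adjoint) and training-mode
batch normalization (fused normalize-scale-shift with the standard
closed-form adjoints). Batch-norm running statistics are updated outside
the autodiff trace with momentum 0.1. Dropout masks and augmentation draws
come from explicit seeded generators, making every training step a pure
function of (parameters, data, seed); deterministic re-runs are part of the
test contract.

## Evaluation

Macro-F1 — the unweighted mean of per-class F1 = 2pr/(p+r) — is the
primary metric; classes absent from both truth and predictions contribute
F1 = 0 (penalizing dropped classes). Reports carry per-class
precision/recall/F1/support, weighted F1, accuracy and the confusion
matrix. Generalization is always measured on *user-disjoint* data: either
fractional splits over the user roster (60/20/20 train/val/test by
largest-remainder rounding of a seed-shuffled roster) or leave-one-subject-
out folds.

## Synthetic data generator

The generator emulates the structure of public smartphone/IMU corpora
without their multi-GB downloads: per activity, a band-limited harmonic
template (3 harmonics per channel, base frequencies spaced over 0.5–8 Hz —
the human movement band; every other activity index has amplitude 0.1
instead of 1.0 so confusable low-energy pairs exist). Each user distorts
every channel by a log-normal multiplicative gain exp(N(0, σ_gain²)), an
additive offset N(0, σ_off²), and one global phase shift N(0, σ_phase²);
i.i.d. Gaussian observation noise is added last. All randomness derives
from one seed through named SHA-256 sub-seeds, so a component (one user's
gain, one recording's noise) is stable when unrelated dimensions change.

Reference conditions (the defaults): 8 users × 6 activities × 6 channels at
50 Hz, 10.5 s per (user, activity) recording → ~120 one-second
50 %-overlap windows per user (960 windows total); σ_gain = 0.4,
σ_off = 0.2, σ_phase = 0.5 rad, noise sd 0.1. At σ_gain = 0 (all user dials
zero) users are interchangeable and a linear probe on summary statistics
separates the activities; at the default σ_gain = 0.4 a supervised-only
model shows a measurable unseen-user deficit — the phenomenon the
multi-task objective targets.

What the generator does **not** model: fall events, activity transitions,
orientation channels, non-stationarity within a recording, or correlated
(non-white) sensor noise. Passing the directional checks on this generator
shows the implementation produces the expected *orderings* under
controlled user-distortion; it does not certify effect sizes on real
recordings.

## Desk-scale study conditions

The published per-dataset recipes (learning rate 1e-4–3e-4, batch 256,
τ = 0.1, λ = 0.2–0.4, 100–200 epochs, patience 30, projection hidden width
256) are available as the `mobiact` / `ucihar` / `uschad` presets. The
bundled `synthetic` preset scales the same recipe to the reference dataset
so the full seven-variant ablation (supervised; 3 strategies × {multi-task,
two-stage}) over five user-disjoint splits runs on one CPU: encoder filters
16/32/32, projector 64→32, classifier 64/32, batch 128, AdamW at
learning rate 2e-3 with weight decay 0.01, 20 epochs (pretraining 20,
fine-tuning 20 for the two-stage arm). The smaller encoder keeps the
residual architecture and depth; the higher learning rate compensates the
shorter schedule at this small data scale. Convergence was the sizing
criterion: validation macro-F1 plateaus within the epoch budget for every
variant (best epochs typically 15–19), and under-training the comparison
(e.g. 12 epochs) leaves all variants mid-convergence where their ordering
is dominated by noise.

## Numerical and design choices

* Windows are 0-based half-open `[start, start+L)`; stride rounds to ≥1
  sample; trailing partial windows are dropped.
* Resampling: polyphase anti-aliased `resample_poly`, output length
  trimmed to `floor(T·target/input)`; upsampling is refused.
* Standardization (per channel, train-user statistics only, sd floored at
  1e-8) is on by default and disable-able; it is a conventional addition,
  not part of the published procedure.
* Augmentation parameters (jitter sd 0.05 on standardized signals, scale
  sd 0.1, 4 permutation segments, p = 0.5) follow common practice for
  contrastive HAR; scaling and sign flips draw per channel by default with
  a per-window variant behind a flag. Op order is fixed
  (jitter → scaling → channel shuffle → rotation → permutation) for
  reproducibility.
* Projection "size 256" in the published recipe is read as the *hidden*
  width of the head; the output dimension is unspecified there and
  defaults to 128 (32 in the synthetic preset).
* Classifier hidden widths are unspecified in the source recipe; defaults
  (256, 128) put the full-size total parameter count in the ~0.55–0.6 M
  band. Dropout 0.2.
* Ties in argmax predictions resolve to the lowest class index.
* Early stopping monitors validation macro-F1; the metric used for this
  purpose is not pinned down by the published recipe, and macro-F1 is the
  natural choice given it is the primary metric.

## Known limitations

* The backend is CPU numpy autodiff: ~2 orders of magnitude slower than a
  GPU tensor framework, which is why the bundled study conditions are
  deliberately small. The architecture and objectives are full-fidelity.
* Adapters for the public corpora (MobiAct, UCI HAR, USC-HAD) are not
  bundled; any dataset exported to the long CSV or packed HDF5 format runs
  through the same pipeline.
* Mixed-activity streams are out of scope: recordings are single-activity
  and windows inherit the recording label.
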