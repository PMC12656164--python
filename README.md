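# supconhar

Multi-task supervised contrastive learning for **user-generalizable**
wearable-sensor human activity recognition (HAR).

## The problem

HAR classifiers eat fixed-length windows of multichannel inertial signals
(accelerometer + gyroscope, typically 50 Hz) and predict an activity class.
In deployment they meet people who were never in the training set, and
inertial signals differ strongly across people (body shape, gait, sensor
placement), so models that look excellent on held-out *windows* of their
training users often degrade sharply on held-out *users*.

This package trains the classifier jointly with a **user-aware supervised
contrastive objective** in a single stage. For an anchor window embedding
z_i with activity label y_act and user label y_user:

* positives P(i): same activity, **different** user — pull cross-user
  examples of one activity together;
* hard negatives: same user, **different** activity — push apart the
  user-specific shortcuts a classifier would otherwise exploit.

The contrastive loss on ℓ2-normalized projection-head embeddings with
temperature τ,

    L_CL = Σ_i −1/|P(i)| Σ_{p∈P(i)} log exp(z_i·z_p/τ) / Σ_{a∈A(i)} exp(z_i·z_a/τ),

is combined with the cross-entropy of the classification head on the raw
(un-augmented) windows: **L = L_CE + λ·L_CL**. The encoder receives both
gradients, the classifier only ∂L_CE, the projection head only λ∂L_CL.
At inference the projection head is discarded: prediction is encoder →
classifier on raw windows, with no per-user adaptation.

The package ships the full apparatus around that objective: a 1-D residual
convolutional encoder, the five standard inertial augmentations (jitter,
scaling, channel shuffle, sign flips, segment permutation) with two-view
generation, user-disjoint fractional and leave-one-subject-out splitting,
NT-Xent and activity-only contrastive baselines, the two-stage
pretrain-then-freeze protocol as an ablation arm, macro-F1 evaluation
reports, and a synthetic wearable-signal generator with controllable
per-user distortions so everything is testable without downloads.

## Worked example

```python
from supconhar import MultiTaskSupConHAR, SyntheticSpec, make_dataset
from supconhar.prep import concat_window_sets, make_windows
from supconhar.config import preset

# 8 synthetic users x 6 activities with realistic per-user distortions
spec = SyntheticSpec()          # the package's reference conditions
recs = make_dataset(spec)       # one recording per (user, activity)
windows = concat_window_sets([make_windows(r, n_classes=6) for r in recs])

cfg = preset("synthetic")       # desk-scale training recipe
est = MultiTaskSupConHAR(windows, arch=cfg.arch, train_config=cfg.train,
                         policy=cfg.policy)
res = est.fit(seed=0)           # 60/20/20 user-disjoint split, then training
print(res.summary())
```

prints:

```
Multi-task supervised contrastive HAR — fit summary
=======================================================
mode: multi_task   strategy: activity_user_hard   lambda: 0.3   tau: 0.1
parameters: encoder 32,960  projector 4,192  classifier 4,390  total 41,542
epochs run: 20  best epoch: 19  (max_epochs reached)
held-out (unseen) test users: u07

       precision  recall     f1  support
class
0         1.0000  1.0000 1.0000       20
1         0.4762  1.0000 0.6452       20
2         1.0000  1.0000 1.0000       20
3         0.0000  0.0000 0.0000       20
4         1.0000  1.0000 1.0000       20
5         1.0000  0.9000 0.9474       20
macro-F1 0.7654  weighted-F1 0.7654  accuracy 0.8167
confusion matrix (rows = true):
[[20  0  0  0  0  0]
 [ 0 20  0  0  0  0]
 [ 0  0 20  0  0  0]
 [ 0 20  0  0  0  0]
 [ 0  0  0  0 20  0]
 [ 0  2  0  0  0 18]]
```

The macro-F1 of 0.7654 is measured **only on a user the model never saw**;
the residual confusion sits exactly where the generator plants it, between
two low-amplitude "static" activities (classes 1 and 3) whose harmonic
templates differ only in frequency. Averaged over five user-disjoint
splits of this dataset, the multi-task configuration scores higher
unseen-user macro-F1 than the supervised-only baseline (0.70 vs 0.66 at
dataset seed 0; 0.79 vs 0.68 at seed 1), and each multi-task strategy
beats its two-stage pretrain-then-freeze counterpart
(`scripts/acceptance.py` recomputes these numbers from scratch).
`res.report` carries the per-class precision/recall/F1 table and the
confusion matrix; `res.history` the per-epoch L_CE/L_CL/validation curves.

The same pipeline is scriptable from the shell:

```bash
supconhar synth --users 8 --activities 6 --seed 1 --out data/
supconhar train --preset synthetic --mode multi_task --seed 1 --out runs/demo
supconhar ablate --grid grids/strategies.yaml --n-runs 3 --out ablation.csv
```

Presets `mobiact`, `ucihar`, `uschad` carry the published full-scale
training recipes (encoder 64/128/128, batch 256, τ=0.1, λ=0.2–0.4) for data
supplied in the long-CSV or packed-HDF5 formats.

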