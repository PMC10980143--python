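# wristgait

Self-supervised gait detection from wrist-worn accelerometer recordings,
aimed at free-living studies of older adults, where labeled gait data are
scarce but unlabeled wear time is abundant.

Walking produces a quasi-periodic oscillation at the step frequency
(≈ 1.5–2.2 Hz at the wrist) that must be separated from broadband arm
activity, tremor, stillness and off-body time. `wristgait` implements the
full analysis chain:

1. **Preprocessing** — resample tri-axial recordings to 30 Hz, cut
   non-overlapping 10 s windows, label a window gait when annotated gait
   covers at least half of it.
2. **Self-supervised pretraining** of a 1-D residual encoder, by either
   * the **multi-task pretext**: each window is randomly reversed,
     segment-permuted, time-warped and axis-scaled (p = 0.5 each) and a
     four-logit head predicts which transforms were applied, with loss
     `mean_j BCE_j` (chance level ln 2); or
   * the **contrastive pretext** (SimCLR-style): two uniformly random 3-D
     rotations of each window are positives under the NT-Xent loss
     `ℓ_i = −log exp(cos(z_i, z_j)/τ) / Σ_{k≠i} exp(cos(z_i, z_k)/τ)`.
3. **Fine-tuning** — subject-wise 75/25 split, grouped stratified 5-fold
   cross-validation over 3 seeds, all weights trainable, linear binary
   head, early stopping (patience 5) on validation loss, selection by F1.
4. **Daily-living post-processing** — non-wear as ≥ 30 min of sub-13 mg
   per-axis SD, the first four full calendar days with ≥ 20 h wear
   (subjects under 96 h excluded), and daily walking time as the median of
   the four per-day gait-window minute sums.
5. **Cohort statistics** — Kruskal-Wallis, Dunn's post-hoc with Bonferroni
   correction, and partial correlation adjusting for age, sex and BMI.

A synthetic free-living signal generator (gait harmonics, arm activity,
tremor, gravity drift, non-wear) with exact ground-truth annotations makes
the whole pipeline runnable and testable without any external data. The
estimators follow scikit-learn conventions (`fit` / `predict` /
`predict_proba`, `get_params`), so they compose with sklearn tooling. The
neural networks run on a small numpy autodiff stack inside the package —
no deep-learning framework is required.

## Worked example

```python
import numpy as np
from wristgait import (
    GaitWindowClassifier, confusion_metrics, predict_windows,
    pretrain_mtl, split_subjects,
)
from wristgait.pipeline import make_learning_corpus

# 30 synthetic subjects (20 min each), split subject-wise 20 train / 10 test,
# plus ~2,000 unlabeled windows from separate subjects for pretraining
train_ws, test_ws, unlabeled = make_learning_corpus(seed=1)

state = pretrain_mtl(unlabeled, n_epochs=12, seed=1)          # SSL pretext
clf = GaitWindowClassifier(init_state=state, random_state=0)  # fine-tune
clf.fit(train_ws)

probs, pred = predict_windows(clf, test_ws)
report = confusion_metrics(test_ws.labels, pred)
print(f"held-out windows: {test_ws.n_windows}  "
      f"gait prevalence: {test_ws.labels.mean():.2f}")
for key in ("accuracy", "specificity", "recall", "precision", "f1"):
    print(f"{key:>12}: {report[key]:6.2f}")
```

prints (≈ 2 minutes on one CPU core):

```
held-out windows: 1200  gait prevalence: 0.15
    accuracy:  98.75
 specificity:  99.31
      recall:  95.60
   precision:  96.13
          f1:  95.87
```

All 1,200 held-out windows come from ten subjects the model never saw;
15 % of them are gait. Accuracy alone is inflated by that imbalance, which
is why recall, precision and F1 are reported — here the fine-tuned model
finds 95.6 % of the gait windows while 96.1 % of its gait calls are
correct.

The same stages are available as a CLI for shell pipelines
(`wristgait simulate | prep | pretrain | finetune | detect | summarize |
evaluate | compare`); every subcommand writes a resolved-config sidecar
next to its outputs so any artifact can be reproduced from the sidecar
alone. A miniature smoke run:

```sh
wristgait simulate --subjects 6 --duration-s 600 --seed 7 --out sim
wristgait prep --input sim/sub_000.csv --annotations sim/sub_000_annotations.csv --out win.h5
wristgait pretrain --method mtl --data win.h5 --epochs 10 --seed 7 --out ssl.npz
wristgait finetune --init ssl.npz --data win.h5 --seed 7 --out model.npz
wristgait detect --model model.npz --data win.h5 --out pred.csv
```

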