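# cogdraw

Screening for mild cognitive impairment (MCI) from three pen-and-paper
drawing tasks — clock drawing, cube copying, and trail making — with a
multi-input convolutional self-attention classifier (**Conv-Att**) that
explains its decisions through attention-rollout heat maps.

The package is aimed at researchers working on automated analysis of
cognitive drawing tests: it provides the full modeling pipeline (data
loading, labeling, training, evaluation, visual explanation) plus a
synthetic drawing generator with ground-truth anomaly masks, so every stage
can be exercised and validated without access to clinical data.

## The model

Each drawing is processed by its own CNN backbone; the last feature map
`X ∈ R^{H×L×C}` is projected by a 1×1 convolution to the attention hidden
dimension `D`, flattened row-major into `HL` tokens, and prefixed with a
learned `[CLS]` token, giving `X̃ ∈ R^{(HL+1)×D}`. A stack of single-head
self-attention encoder layers

    Attn(Q, K, V) = softmax(Q Kᵀ / √D) V,  Q = X̃ W_Qᵀ, K = X̃ W_Kᵀ, V = X̃ W_Vᵀ

aggregates the tokens; the final `[CLS]` vectors of the three task pathways
are concatenated and mapped by a two-node softmax layer to
`(p_healthy, p_MCI)`.

Labels come from the MoCA screening score `m ∈ {0..30}`: hard label
`1[m < 25]`, or the *soft label* `y = 1 − σ(m − 24.5)` which encodes
diagnostic uncertainty near the cutoff. Training minimizes binary
cross-entropy `L = −(1/M) Σ (yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ))` with Adam.

For interpretation, each layer's attention matrix `W_att` is
residual-compensated, `A = 0.5·W_att + 0.5·I`, and rolled out across layers
(`Ã(l_i) = A(l_i)·Ã(l_{i−1})`); the CLS row of the rollout, reshaped to the
feature grid and upsampled, is the per-task heat map. The global-average-
pooling baseline is explained with Grad-CAM instead. Heat maps are scored
against regions of interest (whole-drawing ROIs, or expert/anomaly ROIs) by
top-k% binarization and intersection-over-union.

All networks (a VGG16-configuration backbone and a small 4-block test
backbone, the attention encoder, Adam) are implemented in NumPy with a
compact reverse-mode autodiff core (`cogdraw.nn`), so the package has no
deep-learning-framework dependency.

## Worked example

```python
import numpy as np
from cogdraw import ConvAttClassifier, classification_metrics
from cogdraw.experiments import subjects_to_arrays
from cogdraw.labels import hard_label
from cogdraw.synthetic import simulate_cohort

subs = simulate_cohort(120, "uniform", rng_seed=7, canvas_size=64, noise_sd=1.0)
X, y = subjects_to_arrays(subs)          # (120, 3 tasks, 3, 64, 64), MoCA scores

clf = ConvAttClassifier.toy(epochs=10, random_state=0)   # small CNN, D=32
clf.fit(X[:100], y[:100])
p = clf.predict_proba(X[100:])[:, 1]     # predicted MCI probability
acc, f1, auc = classification_metrics(p, np.asarray(hard_label(y[100:])))
print(f"accuracy={acc:.2f} f1={f1:.2f} auc={auc:.2f}")
```

```
accuracy=0.75 f1=0.71 auc=1.00
```

The held-out subjects are classified as MCI when `p ≥ 0.5`. After this
short 10-epoch run the model already ranks the 20 held-out subjects
perfectly (AUC 1.00) by recovering the severity signal the generator
injected as localized drawing anomalies (misplaced clock hands, broken
cube edges, wrong trail connections, …), while the thresholded accuracy
(0.75) still lags because the probabilities are not yet well calibrated —
at the study scale (300 subjects, 30 epochs; see `docs/methods.md`)
accuracy reaches ≈ 0.81 at AUC ≈ 0.89. Rollout heat maps for the same
subjects come from `cogdraw.explain.rollout_heatmaps(clf, X[100:])`.

A command-line interface mirrors the pipeline stages:

```bash
cogdraw generate --n 300 --seed 1 --canvas-size 64 --out cohort/
cogdraw split --manifest cohort/manifest.csv --seed 1
cogdraw run-all --config config.yaml --out run/
```

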