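"""Scikit-learn style estimators for drawing-based MCI screening.

:class:`ConvAttClassifier` is the proposed model (per-task CNN backbone +
CLS-token self-attention, trained with soft labels by default);
:class:`PoolingBaselineClassifier` is the global-average-pooling CNN
baseline (hard labels by default).  Both follow the sklearn estimator
contract: constructor stores hyperparameters verbatim, ``fit(X, y)`` learns
and sets trailing-underscore attributes, ``get_params``/``set_params`` work
for model selection and cloning.

``X`` is an array of ink-positive images with shape
``(n_subjects, n_tasks, 3, size, size)`` (task axis ordered as ``tasks``);
``y`` holds integer MoCA scores in [0, 30] from which hard or soft training
targets are derived according to ``label_mode``.  ``predict_proba`` returns
``(p_healthy, p_MCI)`` rows; ``predict`` applies the p >= 0.5 MCI rule.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .data import augment
from .labels import DEFAULT_CENTER, DEFAULT_CUTOFF, hard_label, soft_label
from .models import (DEFAULT_FFN_DIM, DEFAULT_HIDDEN_DIM, DEFAULT_N_LAYERS,
                     ConvAttNet, PoolingNet)
from .nn import Adam
from .synthetic import TASKS

__all__ = ["ConvAttClassifier", "PoolingBaselineClassifier", "load_checkpoint"]

_EPS = 1e-7


def _bce(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    from .evaluate import auc_score
    return auc_score(scores, y_true)


class _BaseDrawingClassifier(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery; subclasses build the network."""

    _variant = "base"

    def __init__(self, tasks=TASKS, backbone="vgg16", image_size=256,
                 label_mode="soft", cutoff=DEFAULT_CUTOFF, center=DEFAULT_CENTER,
                 learning_rate=1e-5, beta1=0.9, beta2=0.99, epsilon=1e-7,
                 epochs=100, batch_size=64, augment=True,
                 validation_fraction=0.15, checkpoint_selection="best_auc",
                 random_state=0):
        self.tasks = tasks
        self.backbone = backbone
        self.image_size = image_size
        self.label_mode = label_mode
        self.cutoff = cutoff
        self.center = center
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.epsilon = epsilon
        self.epochs = epochs
        self.batch_size = batch_size
        self.augment = augment
        self.validation_fraction = validation_fraction
        self.checkpoint_selection = checkpoint_selection
        self.random_state = random_state

    # -- subclass hooks -------------------------------------------------
    def _build_net(self, rng: np.random.Generator):
        raise NotImplementedError

    # -- targets --------------------------------------------------------
    def _targets(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y)
        if self.label_mode == "soft":
            return np.asarray(soft_label(y.astype(float), center=self.center))
        if self.label_mode == "hard":
            return np.asarray(hard_label(y, cutoff=self.cutoff), dtype=float)
        raise ValueError(f"label_mode must be 'hard' or 'soft', "
                         f"got {self.label_mode!r}")

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        n_tasks = len(tuple(self.tasks))
        if X.ndim != 5 or X.shape[1] != n_tasks or X.shape[2] != 3:
            raise ValueError(
                f"X must have shape (n, {n_tasks}, 3, S, S); got {X.shape}")
        return X

    # -- training -------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train with Adam on (soft or hard) binary cross-entropy.

        If ``X_val``/``y_val`` are not given and ``validation_fraction > 0``,
        a stratified tail of the data is held out for per-epoch validation
        and checkpoint selection (best validation AUC by default).
        Augmentation (random pad-and-crop translation) applies to training
        images only.  Deterministic under ``random_state``.
        """
        X = self._check_X(X)
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(self.random_state)

        if X_val is None and self.validation_fraction > 0 and len(X) >= 10:
            hard = np.asarray(hard_label(y, cutoff=self.cutoff))
            val_idx = []
            for lbl in (0, 1):
                ids = np.flatnonzero(hard == lbl)
                k = max(1, int(round(len(ids) * self.validation_fraction)))
                val_idx.extend(rng.permutation(ids)[:k])
            val_mask = np.zeros(len(X), dtype=bool)
            val_mask[val_idx] = True
            X_val, y_val = X[val_mask], y[val_mask]
            X, y = X[~val_mask], y[~val_mask]

        t_train = self._targets(y)
        t_val = self._targets(y_val) if y_val is not None else None
        hard_val = (np.asarray(hard_label(np.asarray(y_val), cutoff=self.cutoff))
                    if y_val is not None else None)

        self.net_ = self._build_net(rng)
        opt = Adam(self.net_.parameters(), lr=self.learning_rate,
                   beta1=self.beta1, beta2=self.beta2, eps=self.epsilon)
        history = []
        best = (-np.inf, None)
        for epoch in range(1, self.epochs + 1):
            order = rng.permutation(len(X))
            losses = []
            for start in range(0, len(X), self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = X[idx]
                if self.augment:
                    xb = np.stack([
                        np.stack([augment(img, rng) for img in subj])
                        for subj in xb])
                probs, _ = self.net_.forward(xb)
                p = probs[:, 1].clip(_EPS, 1 - _EPS)
                yb = t_train[idx]
                loss = -((p.log() * yb) + ((1.0 - p).log() * (1.0 - yb))).mean()
                self.net_.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            row = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                   "val_loss": np.nan, "val_auc": np.nan}
            if X_val is not None and len(X_val):
                pv = self._forward_proba(X_val)[:, 1]
                row["val_loss"] = _bce(t_val, pv)
                if hard_val is not None and len(np.unique(hard_val)) == 2:
                    row["val_auc"] = _rank_auc(hard_val, pv)
                    if (self.checkpoint_selection == "best_auc"
                            and row["val_auc"] > best[0]):
                        best = (row["val_auc"],
                                [p.data.copy() for p in self.net_.parameters()])
            history.append(row)
        if self.checkpoint_selection == "best_auc" and best[1] is not None:
            for p, w in zip(self.net_.parameters(), best[1]):
                p.data = w
        self.history_ = pd.DataFrame(history)
        self.classes_ = np.array([0, 1])
        self.grid_shape_ = self.net_.grid_shape
        return self

    # -- inference ------------------------------------------------------
    def _forward_proba(self, X: np.ndarray, batch: int = 64) -> np.ndarray:
        out = []
        for start in range(0, len(X), batch):
            probs, _ = self.net_.forward(X[start:start + batch])
            out.append(probs.data)
        return np.concatenate(out)

    def predict_proba(self, X) -> np.ndarray:
        """(p_healthy, p_MCI) per subject; no augmentation at inference."""
        self._require_fitted()
        return self._forward_proba(self._check_X(X))

    def predict(self, X) -> np.ndarray:
        """Hard prediction: 1 (MCI) iff p_MCI >= 0.5."""
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score(self, X, y) -> float:
        """Accuracy against the hard labels derived from MoCA scores ``y``."""
        truth = np.asarray(hard_label(np.asarray(y), cutoff=self.cutoff))
        return float(np.mean(self.predict(X) == truth))

    def _require_fitted(self):
        if not hasattr(self, "net_"):
            raise RuntimeError(
                f"{type(self).__name__} instance is not fitted yet")

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        """Persist weights + config + seed as <path>.npz / <path>.json."""
        self._require_fitted()
        path = Path(path)
        arrays = {f"w{i}": p.data for i, p in enumerate(self.net_.parameters())}
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"variant": self._variant, "params": self.get_params()}
        meta["params"]["tasks"] = list(tuple(self.tasks))
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def _from_checkpoint(cls, path):
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        params = meta["params"]
        params["tasks"] = tuple(params["tasks"])
        est = cls(**params)
        est.net_ = est._build_net(np.random.default_rng(est.random_state))
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(est.net_.parameters()):
            p.data = data[f"w{i}"].astype(np.float32)
        est.classes_ = np.array([0, 1])
        est.history_ = pd.DataFrame()
        return est


class ConvAttClassifier(_BaseDrawingClassifier):
    """Multi-input Conv-Att model with CLS-token self-attention aggregation."""

    _variant = "conv_att"

    def __init__(self, tasks=TASKS, backbone="vgg16", image_size=256,
                 label_mode="soft", cutoff=DEFAULT_CUTOFF, center=DEFAULT_CENTER,
                 n_layers=DEFAULT_N_LAYERS, hidden_dim=DEFAULT_HIDDEN_DIM,
                 ffn_dim=DEFAULT_FFN_DIM,
                 learning_rate=1e-5, beta1=0.9, beta2=0.99, epsilon=1e-7,
                 epochs=100, batch_size=64, augment=True,
                 validation_fraction=0.15, checkpoint_selection="best_auc",
                 random_state=0):
        super().__init__(tasks=tasks, backbone=backbone, image_size=image_size,
                         label_mode=label_mode, cutoff=cutoff, center=center,
                         learning_rate=learning_rate, beta1=beta1, beta2=beta2,
                         epsilon=epsilon, epochs=epochs, batch_size=batch_size,
                         augment=augment,
                         validation_fraction=validation_fraction,
                         checkpoint_selection=checkpoint_selection,
                         random_state=random_state)
        self.n_layers = n_layers
        self.hidden_dim = hidden_dim
        self.ffn_dim = ffn_dim

    def _build_net(self, rng):
        return ConvAttNet(tuple(self.tasks), backbone=self.backbone,
                          n_layers=self.n_layers, hidden_dim=self.hidden_dim,
                          ffn_dim=self.ffn_dim, rng=rng)

    def attention_traces(self, X) -> dict[str, list[np.ndarray]]:
        """Per-task attention traces for a batch (for rollout heat maps)."""
        self._require_fitted()
        _, traces = self.net_.forward(self._check_X(X))
        return traces

    @classmethod
    def toy(cls, **overrides) -> "ConvAttClassifier":
        """Desk-scale configuration: toy backbone at 64x64, from-scratch
        Adam settings (lr 1e-3, batch 16, <=30 epochs), slim attention
        (D=32, ffn 64).  Translation augmentation is off because the
        synthetic drawings have a fixed canonical layout."""
        params = dict(backbone="toy", image_size=64, hidden_dim=32, ffn_dim=64,
                      learning_rate=1e-3, batch_size=16, epochs=30,
                      augment=False)
        params.update(overrides)
        return cls(**params)


class PoolingBaselineClassifier(_BaseDrawingClassifier):
    """Global-average-pooling CNN baseline (single- or multi-input)."""

    _variant = "pooling_baseline"

    def __init__(self, tasks=TASKS, backbone="vgg16", image_size=256,
                 label_mode="hard", cutoff=DEFAULT_CUTOFF, center=DEFAULT_CENTER,
                 learning_rate=1e-5, beta1=0.9, beta2=0.99, epsilon=1e-7,
                 epochs=100, batch_size=64, augment=True,
                 validation_fraction=0.15, checkpoint_selection="best_auc",
                 random_state=0):
        super().__init__(tasks=tasks, backbone=backbone, image_size=image_size,
                         label_mode=label_mode, cutoff=cutoff, center=center,
                         learning_rate=learning_rate, beta1=beta1, beta2=beta2,
                         epsilon=epsilon, epochs=epochs, batch_size=batch_size,
                         augment=augment,
                         validation_fraction=validation_fraction,
                         checkpoint_selection=checkpoint_selection,
                         random_state=random_state)

    def _build_net(self, rng):
        return PoolingNet(tuple(self.tasks), backbone=self.backbone, rng=rng)

    @classmethod
    def toy(cls, **overrides) -> "PoolingBaselineClassifier":
        params = dict(backbone="toy", image_size=64,
                      learning_rate=1e-3, batch_size=16, epochs=30,
                      augment=False)
        params.update(overrides)
        return cls(**params)


_VARIANTS = {"conv_att": ConvAttClassifier,
             "pooling_baseline": PoolingBaselineClassifier}


def load_checkpoint(path):
    """Load a saved estimator (weights + config + seed)."""
    meta = json.loads(Path(path).with_suffix(".json").read_text())
    return _VARIANTS[meta["variant"]]._from_checkpoint(path)
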