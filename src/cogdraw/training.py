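"""Training surface: BCE loss, training configuration, record-level train loop.

The estimators in :mod:`cogdraw.estimators` own the actual optimization;
this module provides the loss as a standalone function, the configuration
record with the reference optimizer settings (Adam, lr 1e-5, beta1 0.9,
beta2 0.99, eps 1e-7, 100 epochs, batch 64), and wrappers that train and
evaluate directly from subject records and a split assignment.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .data import SplitAssignment, SubjectRecord, records_to_arrays
from .estimators import ConvAttClassifier, PoolingBaselineClassifier

CLAMP = 1e-7

__all__ = ["TrainConfig", "bce_loss", "train", "predict_proba"]


@dataclass
class TrainConfig:
    """Optimizer and schedule settings (defaults = reference settings)."""

    learning_rate: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.99
    epsilon: float = 1e-7
    epochs: int = 100
    batch_size: int = 64
    label_mode: str = "soft"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("rates and sizes must be positive")
        if self.label_mode not in ("hard", "soft"):
            raise ValueError("label_mode must be 'hard' or 'soft'")


def bce_loss(y, p) -> float:
    """Mean binary cross-entropy ``-(1/M) sum(y log p + (1-y) log(1-p))``.

    Targets ``y`` may be hard (0/1) or soft (in [0, 1]); predictions are
    clamped to [1e-7, 1 - 1e-7] for numerical stability.  As a function of
    ``p_i`` the loss is minimized exactly at ``p_i = y_i``.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs p {p.shape}")
    p = np.clip(p, CLAMP, 1 - CLAMP)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _subset(records: list[SubjectRecord], split: SplitAssignment,
            partition: str) -> list[SubjectRecord]:
    ids = set(split.ids(partition))
    return [r for r in records if r.subject_id in ids]


def train(model, records: list[SubjectRecord], split: SplitAssignment,
          config: TrainConfig | None = None):
    """Fit an estimator on the train partition, validating on validation.

    ``model`` is a :class:`ConvAttClassifier` or
    :class:`PoolingBaselineClassifier` (its ``image_size``/architecture
    settings are kept); optimizer settings come from ``config`` when given.
    Returns the fitted model; per-epoch history is in ``model.history_``.
    """
    if config is not None:
        model.set_params(learning_rate=config.learning_rate,
                         beta1=config.beta1, beta2=config.beta2,
                         epsilon=config.epsilon, epochs=config.epochs,
                         batch_size=config.batch_size,
                         label_mode=config.label_mode,
                         random_state=config.seed)
    train_recs = _subset(records, split, "train")
    val_recs = _subset(records, split, "validation")
    if not train_recs or not val_recs:
        raise ValueError("train and validation partitions must be nonempty")
    X_tr, y_tr = records_to_arrays(train_recs, size=model.image_size)
    X_va, y_va = records_to_arrays(val_recs, size=model.image_size)
    return model.fit(X_tr, y_tr, X_val=X_va, y_val=y_va)


def predict_proba(model, records: list[SubjectRecord]) -> pd.DataFrame:
    """Per-subject predicted MCI probability p (no augmentation)."""
    X, _ = records_to_arrays(records, size=model.image_size)
    p = model.predict_proba(X)[:, 1]
    return pd.DataFrame({"subject_id": [r.subject_id for r in records], "p": p})
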