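"""Run configuration: validated, nested, snapshot-able.

A :class:`RunConfig` fans one global seed out to per-stage seeds through a
fixed derivation (``SeedSequence([seed, stage_tag])``) so stages are
individually reproducible without seed collisions.  Unknown keys are
rejected; every pipeline run writes the resolved config next to its
outputs so the snapshot alone reproduces the run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

_STAGE_TAGS = {"generate": 1, "split": 2, "train": 3, "evaluate": 4,
               "explain": 5}


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataConfig(_Section):
    manifest: str | None = None        # load an existing cohort ...
    n_subjects: int = 300              # ... or generate one
    canvas_size: int = 64
    noise_sd: float = 1.0
    severity_distribution: str | float = "uniform"


class LabelConfig(_Section):
    cutoff: int = 25
    center: float = 24.5
    mode: str = "soft"


class ModelConfig(_Section):
    variant: str = "conv_att"          # conv_att | pooling_baseline
    inputs: tuple[str, ...] = ("clock", "cube", "trail")
    backbone: str = "toy"              # vgg16 | toy
    n_layers: int = 2
    hidden_dim: int = 32
    ffn_dim: int = 64


class TrainingConfig(_Section):
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.99
    epsilon: float = 1e-7
    epochs: int = 30
    batch_size: int = 32
    augment: bool = True
    checkpoint_selection: str = "best_auc"


class ExplainConfig(_Section):
    method: str = "rollout"            # rollout | gradcam
    top_k: float = 20.0


class EvaluateConfig(_Section):
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    k_values: tuple[int, ...] = tuple(range(10, 81, 10))
    roi_shape: str = "circle"
    roi_margin_px: int = 5
    ink_threshold: float = 0.5


class RunConfig(_Section):
    seed: int = 0
    out_dir: str = "run"
    data: DataConfig = DataConfig()
    label: LabelConfig = LabelConfig()
    model: ModelConfig = ModelConfig()
    training: TrainingConfig = TrainingConfig()
    explain: ExplainConfig = ExplainConfig()
    evaluate: EvaluateConfig = EvaluateConfig()

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        tag = _STAGE_TAGS[stage]
        return int(np.random.SeedSequence([self.seed, tag])
                   .generate_state(1)[0] % (2 ** 31))

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=False))
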