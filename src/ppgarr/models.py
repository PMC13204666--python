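"""Architectures: 1-D VGG baseline and the VGG-BiLSTM hybrid.

The backbone is three convolutional blocks of increasing width (defaults
64/128/256). Each block is two [Conv1d(k=3, same padding) -> BatchNorm ->
ReLU] units followed by max pooling with stride 2, so the temporal axis
falls 1000 -> 500 -> 250 -> 125 while channels grow. The hybrid variant
transposes the backbone output to (batch, time, channels) and runs two
stacked bidirectional LSTM layers (128 hidden units per direction), giving
256 features per step; flattening 256 x 125 yields the 32,000-wide vector
consumed by a 4096-4096-6 fully connected classifier with ReLU, 50% dropout
and a softmax output. With the default widths the baseline (no BiLSTM) and
hybrid flatten to the same 32,000 features, so the classifiers are
interchangeable.

A pure-recurrent variant (``use_backbone=False``) feeds the transposed raw
multi-view sequence straight into the BiLSTM stack — the architecture used
as the recurrent-only ablation arm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .exceptions import ConfigurationError
from .nn import (
    BatchNorm1d, BiLSTM, Conv1d, Dropout, Flatten, Linear, MaxPool1d,
    ReLU, Sequential, Softmax, Transpose,
)


@dataclass
class ConvBlockSpec:
    """One VGG block: two conv(k=3)+BN+ReLU units then stride-2 max pooling."""

    in_channels: int
    out_channels: int
    conv_layers_per_block: int = 2
    kernel_size: int = 3
    pool_stride: int = 2


@dataclass
class ModelConfig:
    """Full architecture hyperparameters with the study defaults.

    ``use_bilstm`` switches between the VGG baseline and the hybrid;
    ``use_backbone=False`` gives the recurrent-only ablation arm;
    ``input_channels=1`` gives the "PPG only" arm.
    """

    input_channels: int = 3
    input_length: int = 1000
    block_widths: tuple[int, ...] = (64, 128, 256)
    conv_layers_per_block: int = 2
    kernel_size: int = 3
    pool_stride: int = 2
    bilstm_layers: int = 2
    bilstm_hidden_per_direction: int = 128
    classifier_hidden: tuple[int, ...] = (4096, 4096)
    dropout: float = 0.5
    num_classes: int = 6
    use_bilstm: bool = True
    use_backbone: bool = True

    def __post_init__(self) -> None:
        self.block_widths = tuple(self.block_widths)
        self.classifier_hidden = tuple(self.classifier_hidden)
        if self.input_channels not in (1, 3):
            raise ConfigurationError("input_channels must be 1 or 3")
        if self.input_length < 2 or self.num_classes < 2:
            raise ConfigurationError("non-positive or degenerate dimensions")
        if self.use_backbone and any(w <= 0 for w in self.block_widths):
            raise ConfigurationError("block widths must be positive")
        if not self.use_backbone and not self.use_bilstm:
            raise ConfigurationError(
                "at least one of use_backbone/use_bilstm must be enabled")
        if not 0 <= self.dropout < 1:
            raise ConfigurationError("dropout must be in [0, 1)")

    @property
    def num_blocks(self) -> int:
        return len(self.block_widths) if self.use_backbone else 0

    @property
    def backbone_out_length(self) -> int:
        """Temporal length after the pooling cascade (floor halving)."""
        L = self.input_length
        for _ in range(self.num_blocks):
            L //= self.pool_stride
        return L

    @property
    def sequence_width(self) -> int:
        """Feature width per time step entering the BiLSTM (or flatten)."""
        return self.block_widths[-1] if self.use_backbone else self.input_channels

    @property
    def flattened_dim(self) -> int:
        """Width of the flattened vector entering the classifier.

        Defaults: 256 channels x 125 steps = 32,000 for the baseline, and
        2 x 128 x 125 = 32,000 for the hybrid.
        """
        per_step = (2 * self.bilstm_hidden_per_direction if self.use_bilstm
                    else self.sequence_width)
        return per_step * self.backbone_out_length

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))


def build_backbone(cfg: ModelConfig,
                   rng: Optional[np.random.Generator] = None) -> Sequential:
    """Convolutional feature extractor: (B, C_in, L) -> (B, widths[-1], L / 2^k)."""
    rng = rng or np.random.default_rng()
    layers: list = []
    in_ch = cfg.input_channels
    for width in cfg.block_widths:
        for _ in range(cfg.conv_layers_per_block):
            layers += [Conv1d(in_ch, width, cfg.kernel_size, rng=rng),
                       BatchNorm1d(width), ReLU()]
            in_ch = width
        layers.append(MaxPool1d(cfg.pool_stride))
    return Sequential(*layers)


def bilstm_head(cfg: ModelConfig,
                rng: Optional[np.random.Generator] = None) -> Sequential:
    """Transpose (B, C, T) -> (B, T, C) and run the stacked BiLSTM.

    Output is (B, T, 2 * hidden): sequence length preserved, per-step width
    the concatenation of forward and backward hidden states.
    """
    rng = rng or np.random.default_rng()
    return Sequential(
        Transpose(),
        BiLSTM(cfg.sequence_width, cfg.bilstm_hidden_per_direction,
               cfg.bilstm_layers, rng=rng),
    )


def classifier_head(cfg: ModelConfig,
                    rng: Optional[np.random.Generator] = None) -> Sequential:
    """Fully connected classifier: (B, flattened_dim) -> (B, C) probabilities."""
    rng = rng or np.random.default_rng()
    layers: list = []
    in_dim = cfg.flattened_dim
    for width in cfg.classifier_hidden:
        layers += [Linear(in_dim, width, init="he", rng=rng), ReLU(),
                   Dropout(cfg.dropout, rng=rng)]
        in_dim = width
    layers += [Linear(in_dim, cfg.num_classes, init="xavier", rng=rng), Softmax()]
    return Sequential(*layers)


class RhythmNet:
    """A built network: staged composition with feature-export access.

    ``__call__`` returns class probabilities; :meth:`features` returns the
    flattened penultimate representation (the export hook for external
    embedding tools such as t-SNE).
    """

    def __init__(self, cfg: ModelConfig, seed: int = 42):
        self.cfg = cfg
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        stages: list[tuple[str, Sequential]] = []
        if cfg.use_backbone:
            stages.append(("backbone", build_backbone(cfg, self.rng)))
        if cfg.use_bilstm:
            stages.append(("bilstm", bilstm_head(cfg, self.rng)))
        stages.append(("flatten", Sequential(Flatten())))
        stages.append(("classifier", classifier_head(cfg, self.rng)))
        self.stages = stages

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for _, stage in self.stages:
            x = stage.forward(x, training)
        return x

    __call__ = forward

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Evaluation-mode probabilities, computed in minibatches."""
        outs = [self.forward(x[i:i + batch_size], training=False)
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    def features(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Flattened penultimate features (width = cfg.flattened_dim)."""
        outs = []
        for i in range(0, len(x), batch_size):
            h = x[i:i + batch_size]
            for name, stage in self.stages:
                if name == "classifier":
                    break
                h = stage.forward(h, training=False)
            outs.append(h)
        return np.concatenate(outs, axis=0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for _, stage in reversed(self.stages):
            dout = stage.backward(dout)
        return dout

    # -- parameters ---------------------------------------------------------
    def parameters(self):
        return [p for _, stage in self.stages for p in stage.params()]

    @property
    def num_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p.value.copy()
                for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ConfigurationError("checkpoint does not match architecture")
        for i, p in enumerate(params):
            value = np.asarray(state[f"param_{i}"])
            if value.shape != p.value.shape:
                raise ConfigurationError(
                    f"shape mismatch for parameter {i}: "
                    f"{value.shape} vs {p.value.shape}")
            p.value[...] = value

    # -- checkpointing ------------------------------------------------------
    def save_checkpoint(self, path, extra: Optional[dict] = None) -> None:
        """Weights as NPZ plus a JSON sidecar with the auditable config."""
        path = Path(path)
        np.savez(path, **self.state_dict())
        sidecar = {"model_config": asdict(self.cfg), "seed": self.seed}
        sidecar.update(extra or {})
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load_checkpoint(cls, path) -> "RhythmNet":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg = ModelConfig(**sidecar["model_config"])
        net = cls(cfg, seed=sidecar.get("seed", 42))
        with np.load(path if path.suffix else path.with_suffix(".npz")) as z:
            net.load_state_dict(dict(z))
        return net


def build_model(cfg: ModelConfig, seed: int = 42) -> RhythmNet:
    """Build the configured network (baseline, hybrid, or recurrent-only)."""
    return RhythmNet(cfg, seed=seed)
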