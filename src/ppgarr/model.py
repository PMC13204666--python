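"""Statsmodels-style front end: a model object fitted to a labeled dataset.

``RhythmClassifier`` bundles the whole pipeline — derivative enhancement,
stratified splitting, network construction, optimization — behind one
object; ``fit()`` returns a ``RhythmClassifierResults`` carrying the
trained network, training history, split and test-set metrics, with a
``summary()`` table in the spirit of a regression results printout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import LabeledDataset, SplitResult, stratified_split
from .evaluation import MetricsReport, evaluate, round_half_up
from .exceptions import InvalidInputError
from .models import ModelConfig, RhythmNet, build_model
from .signals import enhance_batch
from .training import TrainingConfig, TrainingState, train


class RhythmClassifier:
    """Six-class PPG rhythm classifier specified on a labeled dataset.

    Parameters
    ----------
    dataset : LabeledDataset
        NxL segments with labels 0-5.
    model_config, training_config : optional
        Architecture and optimization hyperparameters (study defaults).
    boundary_mode : str
        Boundary policy of the backward differences.
    split_ratios : tuple
        Train/val/test fractions of the two-stage stratified split.
    """

    def __init__(self, dataset: LabeledDataset,
                 model_config: Optional[ModelConfig] = None,
                 training_config: Optional[TrainingConfig] = None,
                 boundary_mode: str = "extrapolate_continuous",
                 split_ratios: Sequence[float] = (0.6, 0.2, 0.2)):
        self.dataset = dataset
        self.model_config = model_config or ModelConfig(
            input_length=dataset.segment_length)
        self.training_config = training_config or TrainingConfig()
        self.boundary_mode = boundary_mode
        self.split_ratios = tuple(split_ratios)
        if self.model_config.input_length != dataset.segment_length:
            raise InvalidInputError(
                f"model expects length {self.model_config.input_length}, "
                f"dataset has {dataset.segment_length}")

    @classmethod
    def from_arrays(cls, segments: np.ndarray, labels: np.ndarray,
                    **kwargs) -> "RhythmClassifier":
        return cls(LabeledDataset(segments, labels), **kwargs)

    def enhance(self, segments: np.ndarray) -> np.ndarray:
        """NxL raw segments -> NxCxL normalized multi-view input."""
        return enhance_batch(segments, boundary_mode=self.boundary_mode,
                             channels=self.model_config.input_channels)

    def fit(self, verbose: bool = False) -> "RhythmClassifierResults":
        """Enhance, split, build and train; returns the results object."""
        X = self.enhance(self.dataset.segments)
        y = self.dataset.labels
        split = stratified_split(self.dataset, self.split_ratios,
                                 seed=self.training_config.seed)
        net = build_model(self.model_config, seed=self.training_config.seed)
        net, state = train(net, (X[split.train_idx], y[split.train_idx]),
                           (X[split.val_idx], y[split.val_idx]),
                           self.training_config, verbose=verbose)
        return RhythmClassifierResults(self, net, state, split)


@dataclass
class RhythmClassifierResults:
    """Fitted classifier: trained net, history, split and metrics."""

    model: RhythmClassifier
    net: RhythmNet
    training_state: TrainingState
    split: SplitResult

    def __post_init__(self) -> None:
        self._reports: dict[str, MetricsReport] = {}

    @property
    def history(self) -> pd.DataFrame:
        return self.training_state.history_frame

    def _split_indices(self, split: str) -> np.ndarray:
        try:
            return {"train": self.split.train_idx, "val": self.split.val_idx,
                    "test": self.split.test_idx}[split]
        except KeyError:
            raise InvalidInputError(
                f"split must be train/val/test, got {split!r}") from None

    def predict(self, segments: np.ndarray) -> np.ndarray:
        return self.net.predict(self.model.enhance(segments))

    def predict_proba(self, segments: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self.model.enhance(segments))

    def features(self, segments: np.ndarray) -> np.ndarray:
        """Penultimate-layer features for external embedding tools."""
        return self.net.features(self.model.enhance(segments))

    def export_features(self, path, segments: Optional[np.ndarray] = None,
                        split: str = "test") -> None:
        if segments is None:
            idx = self._split_indices(split)
            segments = self.model.dataset.segments[idx]
        np.savez(path, features=self.features(segments))

    def evaluate(self, split: str = "test") -> MetricsReport:
        """Metric suite (with CIs) on one partition; cached per split."""
        if split not in self._reports:
            idx = self._split_indices(split)
            ds = self.model.dataset
            y_pred = self.predict(ds.segments[idx])
            self._reports[split] = evaluate(ds.labels[idx], y_pred)
        return self._reports[split]

    def summary(self) -> str:
        """Human-readable fit summary: run facts plus the test-set table."""
        st = self.training_state
        report = self.evaluate("test")
        cfg = self.model.model_config
        arch = ("VGG-BiLSTM" if cfg.use_backbone and cfg.use_bilstm
                else "VGG" if cfg.use_backbone else "BiLSTM")
        lines = [
            "PPG Rhythm Classifier Results",
            "=" * 64,
            f"Architecture:        {arch} "
            f"(channels={cfg.input_channels}, widths={cfg.block_widths if cfg.use_backbone else '-'})",
            f"Parameters:          {self.net.num_params:,}",
            f"Train/val/test:      {self.split.sizes[0]}/{self.split.sizes[1]}"
            f"/{self.split.sizes[2]} (seed {self.split.seed})",
            f"Epochs run:          {st.epoch} (best epoch {st.best_epoch}, "
            f"best val loss {st.best_val_loss:.4f})",
            f"Test accuracy:       "
            f"{round_half_up(report.accuracy):.1f}% "
            f"({round_half_up(report.accuracy_ci[0]):.1f}–"
            f"{round_half_up(report.accuracy_ci[1]):.1f})",
            "",
            report.to_markdown(),
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Training/validation loss curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.history
        ax.plot(h["epoch"], h["train_loss"], label="train loss")
        ax.plot(h["epoch"], h["val_loss"], label="val loss")
        ax.set_xlabel("epoch")
        ax.set_ylabel("cross-entropy")
        ax.legend()
        return ax
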