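"""Training loop: Adam, cross-entropy, early stopping on validation loss.

Defaults mirror the study configuration: learning rate 1e-4, batch size 32,
at most 200 epochs, and early stopping once validation loss fails to
improve for 20 consecutive epochs, with the best-validation weights
restored at the end.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InvalidInputError, TrainingDivergedError
from .models import RhythmNet
from .nn import Adam

LOG_CLIP = 1e-12


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    seed: int = 42
    min_delta: float = 0.0
    restore_best: bool = True
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.patience) <= 0:
            raise ConfigurationError("learning_rate, batch_size, max_epochs "
                                     "and patience must be positive")
        if self.patience >= self.max_epochs:
            raise ConfigurationError("patience must be smaller than max_epochs")
        if self.min_delta < 0:
            raise ConfigurationError("min_delta must be non-negative")


@dataclass
class TrainingState:
    """Early-stopping bookkeeping plus the per-epoch history."""

    epoch: int = 0
    best_val_loss: float = np.inf
    best_epoch: int = 0
    epochs_since_improvement: int = 0
    history: list = field(default_factory=list)

    @property
    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)


def cross_entropy(probs: np.ndarray, labels: np.ndarray,
                  clip: float = LOG_CLIP) -> float:
    """Mean negative log-likelihood of one-hot labels under `probs`.

    ``L = -(1/N) sum_i sum_j y_ij log(p_ij)`` with probabilities clipped at
    `clip` before the log for numerical safety.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.ndim != 2 or labels.shape != (probs.shape[0],):
        raise InvalidInputError("probs must be BxC with one label per row")
    if labels.size and (labels.min() < 0 or labels.max() >= probs.shape[1]):
        raise InvalidInputError("label out of range")
    picked = probs[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.clip(picked, clip, None))))


def _cross_entropy_grad(probs: np.ndarray, labels: np.ndarray,
                        clip: float = LOG_CLIP) -> np.ndarray:
    """dL/dprobs for the mean cross-entropy (before the softmax backward)."""
    B = probs.shape[0]
    grad = np.zeros_like(probs)
    idx = np.arange(B)
    grad[idx, labels] = -1.0 / (np.clip(probs[idx, labels], clip, None) * B)
    return grad


def early_stopping_update(state: TrainingState, val_loss: float,
                          patience: int, min_delta: float = 0.0
                          ) -> tuple[TrainingState, bool]:
    """Advance the early-stopping counter after one validation epoch.

    Improvement means ``val_loss < best - min_delta`` (strict). Returns the
    mutated state and ``stop``, true exactly when the non-improvement streak
    reaches `patience`.
    """
    if not np.isfinite(val_loss):
        raise InvalidInputError("validation loss must be finite")
    state.epoch += 1
    if val_loss < state.best_val_loss - min_delta:
        state.best_val_loss = float(val_loss)
        state.best_epoch = state.epoch
        state.epochs_since_improvement = 0
    else:
        state.epochs_since_improvement += 1
    return state, state.epochs_since_improvement >= patience


def _epoch_eval(model: RhythmNet, X: np.ndarray, y: np.ndarray,
                batch_size: int) -> tuple[float, float]:
    probs = model.predict_proba(X, batch_size)
    return cross_entropy(probs, y), float(np.mean(probs.argmax(axis=1) == y))


def train(model: RhythmNet, train_set: tuple[np.ndarray, np.ndarray],
          val_set: tuple[np.ndarray, np.ndarray],
          cfg: Optional[TrainingConfig] = None,
          verbose: bool = False) -> tuple[RhythmNet, TrainingState]:
    """Fit `model` with Adam + early stopping; returns it with best weights.

    `train_set` / `val_set` are ``(X, y)`` with X of shape (N, C, L) matching
    the model config. Minibatch order is reshuffled every epoch from a
    generator seeded by ``cfg.seed``; a non-finite loss aborts with the
    offending epoch and batch named.
    """
    cfg = cfg or TrainingConfig()
    Xtr, ytr = train_set
    Xva, yva = val_set
    if len(Xtr) == 0 or len(Xva) == 0:
        raise InvalidInputError("train and validation sets must be nonempty")
    ytr = np.asarray(ytr, dtype=int)
    yva = np.asarray(yva, dtype=int)
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate,
                     betas=cfg.adam_betas, eps=cfg.adam_eps)
    state = TrainingState()
    best_weights = None
    n = len(Xtr)
    for epoch in range(1, cfg.max_epochs + 1):
        perm = rng.permutation(n)
        losses = []
        for b, start in enumerate(range(0, n, cfg.batch_size)):
            idx = perm[start:start + cfg.batch_size]
            probs = model.forward(Xtr[idx], training=True)
            loss = cross_entropy(probs, ytr[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch}, batch {b}")
            optimizer.zero_grad()
            model.backward(_cross_entropy_grad(probs, ytr[idx]))
            optimizer.step()
            losses.append(loss)
        val_loss, val_acc = _epoch_eval(model, Xva, yva, cfg.batch_size)
        state.history.append({
            "epoch": epoch, "train_loss": float(np.mean(losses)),
            "val_loss": val_loss, "val_acc": val_acc,
        })
        improved_before = state.best_val_loss
        state, stop = early_stopping_update(state, val_loss, cfg.patience,
                                            cfg.min_delta)
        if state.best_val_loss < improved_before and cfg.restore_best:
            best_weights = copy.deepcopy(model.state_dict())
        if verbose:
            print(f"epoch {epoch:3d}  train {np.mean(losses):.4f}  "
                  f"val {val_loss:.4f}  acc {val_acc:.3f}")
        if stop:
            break
    if cfg.restore_best and best_weights is not None:
        model.load_state_dict(best_weights)
    return model, state


def run_manifest(model: RhythmNet, training_cfg: TrainingConfig,
                 state: TrainingState) -> dict:
    """Everything needed to audit or re-plot a run."""
    return {
        "model_config": asdict(model.cfg),
        "training_config": asdict(training_cfg),
        "seed": training_cfg.seed,
        "best_epoch": state.best_epoch,
        "best_val_loss": (None if not np.isfinite(state.best_val_loss)
                          else state.best_val_loss),
        "epochs_run": state.epoch,
        "history": state.history,
    }


def save_run(out_dir, model: RhythmNet, training_cfg: TrainingConfig,
             state: TrainingState) -> None:
    """Persist checkpoint (+JSON sidecar), history CSV and run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model.save_checkpoint(out / "model.npz", extra={
        "epoch": state.best_epoch,
        "val_loss": None if not np.isfinite(state.best_val_loss)
        else state.best_val_loss,
    })
    state.history_frame.to_csv(out / "history.csv", index=False)
    (out / "manifest.json").write_text(
        json.dumps(run_manifest(model, training_cfg, state), indent=2))
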