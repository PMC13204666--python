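"""Labeled segment datasets, file IO and the two-stage stratified split.

Rhythm labels follow the fixed mapping 0-5 = SR, PVC, PAC, VT, SVT, AF.
The split mimics the two-stage stratified procedure used for imbalanced
arrhythmia corpora: stage 1 divides each class 60:40 into train vs. a
temporary pool, stage 2 halves the pool per class into validation and test.
Per-class fractional allocations are resolved by largest-remainder rounding,
so every partition's per-class count is within 1 of ``ratio * count(class)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, StratificationError

CLASS_NAMES: tuple[str, ...] = ("SR", "PVC", "PAC", "VT", "SVT", "AF")
NUM_CLASSES = len(CLASS_NAMES)

DEFAULT_RATIOS = (0.6, 0.2, 0.2)
DEFAULT_SEED = 42


@dataclass
class LabeledDataset:
    """An NxL matrix of PPG segments with integer rhythm labels 0-5."""

    segments: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES
    fs: float = 100.0

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.segments.ndim != 2:
            raise InvalidInputError("segments must be a 2-D NxL matrix")
        if self.labels.ndim != 1 or self.labels.shape[0] != self.segments.shape[0]:
            raise InvalidInputError(
                "labels must be a vector with one entry per segment row"
            )
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= len(self.class_names)
        ):
            raise InvalidInputError(
                f"labels must lie in 0..{len(self.class_names) - 1}"
            )

    def __len__(self) -> int:
        return self.segments.shape[0]

    @property
    def segment_length(self) -> int:
        return self.segments.shape[1]

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.segments[idx], self.labels[idx], self.class_names, self.fs
        )


@dataclass
class SplitResult:
    """Disjoint train/val/test index sets covering the whole dataset."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    ratios: tuple[float, float, float]
    per_class_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.val_idx = np.asarray(self.val_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train_idx), len(self.val_idx), len(self.test_idx))

    def to_manifest(self) -> dict:
        return {
            "seed": self.seed,
            "ratios": list(self.ratios),
            "sizes": {"train": self.sizes[0], "val": self.sizes[1], "test": self.sizes[2]},
            "per_class_counts": self.per_class_counts,
            "train_idx": self.train_idx.tolist(),
            "val_idx": self.val_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
        }

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_manifest()))


def _largest_remainder_pair(n: int, frac_first: float, tie_to_first: bool) -> int:
    """Allocate ``n`` items between two parts with largest-remainder rounding.

    Returns the size of the first part. Ties (remainders equal, e.g. halving
    an odd count) go to the first part when `tie_to_first`.
    """
    q1 = frac_first * n
    q2 = (1.0 - frac_first) * n
    f1, f2 = int(np.floor(q1)), int(np.floor(q2))
    leftover = n - f1 - f2
    if leftover:
        r1, r2 = q1 - f1, q2 - f2
        if r1 > r2 or (np.isclose(r1, r2) and tie_to_first):
            f1 += 1
    return f1


def stratified_split(
    ds: LabeledDataset,
    ratios: Sequence[float] = DEFAULT_RATIOS,
    seed: int = DEFAULT_SEED,
) -> SplitResult:
    """Two-stage, per-class stratified train/val/test split.

    Stage 1 splits every class into train vs. temporary at
    ``ratios[0] : 1 - ratios[0]``; stage 2 divides each class's temporary
    pool into validation and test at ``ratios[1] : ratios[2]`` (equal halves
    by default, an odd pool giving validation the extra sample). Shuffling
    uses a generator derived from ``(seed, class)`` so the result is
    deterministic and independent of class iteration order.

    Raises
    ------
    StratificationError
        If any class present in the dataset has fewer than 3 members (one
        per partition is then impossible).
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise InvalidInputError("ratios must be three positive numbers")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise InvalidInputError(f"ratios must sum to 1, got {sum(ratios)}")
    if len(ds) == 0:
        raise InvalidInputError("cannot split an empty dataset")

    present = np.unique(ds.labels)
    for c in present:
        n_c = int(np.sum(ds.labels == c))
        if n_c < 3:
            raise StratificationError(
                f"class {c} ({ds.class_names[c]}) has only {n_c} member(s); "
                "stratified splitting needs at least 3 per class"
            )

    stage2_frac = ratios[1] / (ratios[1] + ratios[2])
    train_parts, val_parts, test_parts = [], [], []
    per_class_counts: dict[str, dict[str, int]] = {}
    for c in present:
        idx_c = np.flatnonzero(ds.labels == c)
        rng = np.random.default_rng([seed, int(c)])
        perm = rng.permutation(idx_c)
        n_c = len(perm)
        n_train = _largest_remainder_pair(n_c, ratios[0], tie_to_first=True)
        # guarantee at least one sample per partition
        n_train = min(max(n_train, 1), n_c - 2)
        temp = perm[n_train:]
        n_val = _largest_remainder_pair(len(temp), stage2_frac, tie_to_first=True)
        n_val = min(max(n_val, 1), len(temp) - 1)
        train_parts.append(perm[:n_train])
        val_parts.append(temp[:n_val])
        test_parts.append(temp[n_val:])
        per_class_counts[ds.class_names[c]] = {
            "train": n_train,
            "val": n_val,
            "test": len(temp) - n_val,
        }

    return SplitResult(
        train_idx=np.sort(np.concatenate(train_parts)),
        val_idx=np.sort(np.concatenate(val_parts)),
        test_idx=np.sort(np.concatenate(test_parts)),
        seed=seed,
        ratios=ratios,
        per_class_counts=per_class_counts,
    )


def class_distribution(ds: LabeledDataset) -> pd.DataFrame:
    """Per-class counts and proportions as a DataFrame indexed by class name."""
    if len(ds) == 0:
        raise InvalidInputError("dataset is empty")
    counts = np.bincount(ds.labels, minlength=len(ds.class_names))
    return pd.DataFrame(
        {"count": counts, "proportion": counts / counts.sum()},
        index=list(ds.class_names),
    )


# ---------------------------------------------------------------------------
# File IO: CSV (one segment per row, separate labels file) and NPZ container.

def save_csv(ds: LabeledDataset, segments_path, labels_path) -> None:
    np.savetxt(segments_path, ds.segments, delimiter=",", fmt="%.6g")
    np.savetxt(labels_path, ds.labels[:, None], delimiter=",", fmt="%d")


def load_csv(
    segments_path, labels_path, expected_length: Optional[int] = 1000,
    allow_any_length: bool = False, fs: float = 100.0,
) -> LabeledDataset:
    """Read an NxL segments CSV plus an N-row labels CSV.

    By default rows must have `expected_length` samples (10 s at 100 Hz);
    pass ``allow_any_length=True`` to accept other consistent lengths.
    """
    segments = np.atleast_2d(np.loadtxt(segments_path, delimiter=",", dtype=float))
    labels = np.loadtxt(labels_path, delimiter=",", dtype=int).reshape(-1)
    return _finalize_load(segments, labels, expected_length, allow_any_length, fs)


def save_npz(ds: LabeledDataset, path) -> None:
    np.savez(path, segments=ds.segments, labels=ds.labels, fs=ds.fs)


def load_npz(
    path, expected_length: Optional[int] = 1000,
    allow_any_length: bool = False,
) -> LabeledDataset:
    with np.load(path) as z:
        segments = z["segments"]
        labels = z["labels"]
        fs = float(z["fs"]) if "fs" in z else 100.0
    return _finalize_load(segments, labels, expected_length, allow_any_length, fs)


def _finalize_load(segments, labels, expected_length, allow_any_length, fs):
    if segments.shape[0] != labels.shape[0]:
        raise InvalidInputError(
            f"{segments.shape[0]} segments but {labels.shape[0]} labels"
        )
    if not allow_any_length and expected_length is not None:
        if segments.shape[1] != expected_length:
            raise InvalidInputError(
                f"segments have length {segments.shape[1]}, expected "
                f"{expected_length}; pass allow_any_length=True to override"
            )
    return LabeledDataset(segments, labels, fs=fs)


def save_enhanced_npz(path, enhanced: np.ndarray, labels: np.ndarray) -> None:
    """Persist an Nx3xL enhanced array; channel order is [PPG, VPG, APG]."""
    np.savez(
        path, enhanced=enhanced, labels=np.asarray(labels, dtype=int),
        channel_order=np.array(["PPG", "VPG", "APG"]),
    )
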