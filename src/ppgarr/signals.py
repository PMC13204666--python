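"""Derivative-based multi-view enhancement of PPG segments.

A raw photoplethysmogram (PPG) records relative blood-volume changes. Its
first temporal derivative (the velocity plethysmogram, VPG) and second
derivative (acceleration plethysmogram, APG) expose morphological detail —
upstroke slope, dicrotic-notch dynamics, arterial-stiffness correlates —
that is hard to see in the raw waveform. This module computes those
derivatives with a first-order backward finite difference, z-scores each
channel per segment, and stacks [PPG, VPG, APG] into the 3xL "multi-view"
input consumed by the classifiers.

Backward differences (``out[i] = x[i] - x[i-1]`` for ``i > 0``) use only
current and past samples, so the enhancement is causal and applicable to
streaming data. The first sample has no predecessor; two boundary policies
are offered:

``extrapolate_continuous`` (default)
    ``out[0] = x[1] - x[0]`` — repeats the first interior difference, so a
    linear ramp maps to a constant derivative (waveform continuity).
``literal_eq1``
    ``out[0] = x[0] - (x[1] - x[0])`` — mirror-extrapolates a virtual sample
    before the segment and differences against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import InvalidInputError

BOUNDARY_MODES = ("extrapolate_continuous", "literal_eq1")

DEFAULT_FS = 100.0
DEFAULT_SIGMA_TOLERANCE = 1e-8

#: fixed channel order of the enhanced stack
CHANNEL_NAMES = ("PPG", "VPG", "APG")


@dataclass
class PPGSegment:
    """One fixed-length PPG segment (default 10 s at 100 Hz = 1000 samples).

    Parameters
    ----------
    samples : ndarray
        Waveform in arbitrary amplitude units, length >= 2, all finite.
    fs : float
        Sampling frequency in Hz.
    label : int, optional
        Rhythm class 0-5 (SR, PVC, PAC, VT, SVT, AF).
    subject_id : str, optional
        Identifier of the recording subject.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    label: Optional[int] = None
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        _validate_vector(self.samples)
        if self.fs <= 0:
            raise InvalidInputError(f"sampling frequency must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return len(self) / self.fs


@dataclass
class NormalizationStats:
    """Per-segment z-score statistics (population standard deviation)."""

    mu: float
    sigma: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidInputError("sigma must be non-negative")


@dataclass
class MultiViewSegment:
    """3xL stack of [PPG, VPG, APG] channels, optionally z-scored per channel."""

    channels: np.ndarray
    normalized: bool = False
    stats: tuple = field(default=())

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != 3:
            raise InvalidInputError(
                f"channels must be a 3xL matrix, got shape {self.channels.shape}"
            )

    @property
    def length(self) -> int:
        return self.channels.shape[1]


def _validate_vector(x: np.ndarray, min_length: int = 2) -> None:
    if x.ndim != 1:
        raise InvalidInputError(f"expected a 1-D vector, got ndim={x.ndim}")
    if x.shape[0] < min_length:
        raise InvalidInputError(
            f"need at least {min_length} samples, got {x.shape[0]}"
        )
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("input contains non-finite values")


def backward_difference(
    x: np.ndarray, boundary_mode: str = "extrapolate_continuous"
) -> np.ndarray:
    """First-order backward difference with length-preserving boundary.

    ``out[i] = x[i] - x[i-1]`` for every interior index; ``out[0]`` follows
    `boundary_mode` (see module docstring). Output length equals input
    length.
    """
    x = np.asarray(x, dtype=float)
    _validate_vector(x)
    if boundary_mode not in BOUNDARY_MODES:
        raise InvalidInputError(
            f"unknown boundary_mode {boundary_mode!r}; expected one of {BOUNDARY_MODES}"
        )
    out = np.empty_like(x)
    out[1:] = x[1:] - x[:-1]
    first = x[1] - x[0]
    out[0] = first if boundary_mode == "extrapolate_continuous" else x[0] - first
    return out


def compute_vpg(
    segment: PPGSegment, boundary_mode: str = "extrapolate_continuous"
) -> np.ndarray:
    """Velocity plethysmogram: first backward difference of the raw PPG."""
    return backward_difference(segment.samples, boundary_mode)


def compute_apg(
    segment: PPGSegment, boundary_mode: str = "extrapolate_continuous"
) -> np.ndarray:
    """Acceleration plethysmogram: backward difference applied to the VPG."""
    if len(segment) < 3:
        raise InvalidInputError("APG requires at least 3 samples")
    return backward_difference(compute_vpg(segment, boundary_mode), boundary_mode)


def zscore(
    x: np.ndarray, sigma_tolerance: float = DEFAULT_SIGMA_TOLERANCE
) -> tuple[np.ndarray, NormalizationStats]:
    """Per-segment z-score with the population standard deviation.

    ``out = (x - mu) / sigma`` where ``mu`` is the arithmetic mean and
    ``sigma`` the population (denominator N) standard deviation of the
    segment. A segment flatter than `sigma_tolerance` (e.g. a sensor
    dropout) yields an all-zero output with ``degenerate=True`` rather than
    an error, so batch pipelines keep running.
    """
    x = np.asarray(x, dtype=float)
    _validate_vector(x)
    mu = float(np.mean(x))
    sigma = float(np.std(x))  # ddof=0: population
    if sigma < sigma_tolerance:
        return np.zeros_like(x), NormalizationStats(mu, sigma, degenerate=True)
    return (x - mu) / sigma, NormalizationStats(mu, sigma, degenerate=False)


def enhance(
    segment: PPGSegment,
    boundary_mode: str = "extrapolate_continuous",
    normalize_each_channel: bool = True,
    sigma_tolerance: float = DEFAULT_SIGMA_TOLERANCE,
) -> MultiViewSegment:
    """Build the 3xL multi-view stack [PPG, VPG, APG] for one segment.

    Derivatives are computed from the *raw* segment; each channel is then
    z-scored independently when `normalize_each_channel` is set. Independent
    per-channel normalization matters because VPG/APG amplitudes are orders
    of magnitude below the raw PPG.
    """
    ppg = segment.samples
    vpg = compute_vpg(segment, boundary_mode)
    apg = compute_apg(segment, boundary_mode)
    rows = [ppg, vpg, apg]
    stats: list[NormalizationStats] = []
    if normalize_each_channel:
        normed = []
        for row in rows:
            z, st = zscore(row, sigma_tolerance)
            normed.append(z)
            stats.append(st)
        rows = normed
    return MultiViewSegment(
        channels=np.vstack(rows),
        normalized=normalize_each_channel,
        stats=tuple(stats),
    )


def enhance_batch(
    segments: np.ndarray,
    boundary_mode: str = "extrapolate_continuous",
    normalize_each_channel: bool = True,
    channels: int = 3,
    sigma_tolerance: float = DEFAULT_SIGMA_TOLERANCE,
    dtype=np.float32,
) -> np.ndarray:
    """Vectorized enhancement of an NxL segment matrix to Nx3xL (or Nx1xL).

    With ``channels=1`` only the z-scored raw PPG is emitted — the input of
    the "PPG only" ablation arm. Semantics per row match :func:`enhance`.
    """
    segments = np.asarray(segments, dtype=float)
    if segments.ndim != 2 or segments.shape[1] < 3:
        raise InvalidInputError("segments must be an NxL matrix with L >= 3")
    if boundary_mode not in BOUNDARY_MODES:
        raise InvalidInputError(f"unknown boundary_mode {boundary_mode!r}")
    if channels not in (1, 3):
        raise InvalidInputError("channels must be 1 or 3")
    if not np.all(np.isfinite(segments)):
        raise InvalidInputError("segments contain non-finite values")

    def _diff(mat: np.ndarray) -> np.ndarray:
        out = np.empty_like(mat)
        out[:, 1:] = mat[:, 1:] - mat[:, :-1]
        first = mat[:, 1] - mat[:, 0]
        out[:, 0] = first if boundary_mode == "extrapolate_continuous" else mat[:, 0] - first
        return out

    stack = [segments]
    if channels == 3:
        vpg = _diff(segments)
        stack += [vpg, _diff(vpg)]
    out = np.stack(stack, axis=1)
    if normalize_each_channel:
        mu = out.mean(axis=2, keepdims=True)
        sigma = out.std(axis=2, keepdims=True)
        good = sigma >= sigma_tolerance
        out = np.where(good, (out - mu) / np.where(good, sigma, 1.0), 0.0)
    return out.astype(dtype)
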