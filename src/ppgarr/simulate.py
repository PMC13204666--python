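"""Synthetic six-rhythm PPG generator.

A desk-scale stand-in for clinical PPG corpora: each segment is a train of
pulse waves whose beat-timing statistics carry the rhythm class, rendered
as Gaussians plus noise and baseline wander. The classes differ in exactly
the features a rhythm classifier must exploit:

* SR  — regular ~75 bpm (mean RR 0.8 s, small jitter).
* PVC — SR base with occasional premature ectopic beats that are *large and
  wide* (ventricular morphology) and followed by a compensatory pause.
* PAC — SR base with premature ectopic beats that are *small* (atrial
  morphology) and no full compensatory pause.
* VT  — sustained ~170 bpm with low-amplitude, widened, partially merged
  pulses.
* SVT — sustained ~170 bpm with normal pulse morphology.
* AF  — "irregularly irregular": SR-like rate with very large RR jitter.

Each beat renders as a systolic Gaussian (full width at half maximum
0.10 s times the beat's width multiplier) plus a dicrotic Gaussian at 0.35x
the amplitude delayed by 0.25 s. Rendering is additive over beats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .dataset import CLASS_NAMES, LabeledDataset
from .exceptions import InvalidInputError
from .signals import PPGSegment

#: Gaussian sigma for a unit-width systolic pulse: FWHM 0.10 s.
SYSTOLIC_SIGMA = 0.10 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
DICROTIC_DELAY = 0.25      # s after the systolic peak
DICROTIC_AMPLITUDE = 0.35  # fraction of the systolic amplitude
RR_FLOOR = 0.25            # s; truncation floor preventing beat overlap
AMPLITUDE_JITTER_SD = 0.05


@dataclass
class RhythmSpec:
    """Beat-timing and morphology statistics for one rhythm class."""

    rhythm_class: int
    mean_rr: float
    rr_jitter_sd: float
    ectopic_probability: float = 0.0
    ectopic_prematurity: float = 0.0
    ectopic_amplitude_scale: float = 1.0
    ectopic_width_scale: float = 1.0
    compensatory_pause: bool = False
    beat_amplitude_scale: float = 1.0
    beat_width_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise InvalidInputError("mean_rr must be positive")
        if not 0 <= self.ectopic_probability <= 1:
            raise InvalidInputError("ectopic_probability must be in [0, 1]")


@dataclass
class BeatTrain:
    """Beat times (strictly increasing, within the window) and multipliers."""

    beat_times: np.ndarray
    amplitudes: np.ndarray
    widths: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.beat_times.size:
            if np.any(np.diff(self.beat_times) <= 0):
                raise InvalidInputError("beat times must be strictly increasing")
            if self.beat_times[0] < 0 or self.beat_times[-1] >= self.duration:
                raise InvalidInputError("beat times must lie in [0, duration)")


@dataclass
class SimConfig:
    """Segment geometry, noise levels and per-class counts."""

    duration: float = 10.0
    fs: float = 100.0
    noise_sd: float = 0.05
    wander_amplitude: float = 0.3
    wander_frequency: float = 0.25
    seed: int = 42
    class_counts: tuple[int, ...] = (100,) * len(CLASS_NAMES)

    def __post_init__(self) -> None:
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise InvalidInputError("duration x fs must be an integer")
        self.class_counts = tuple(int(c) for c in self.class_counts)
        if any(c < 0 for c in self.class_counts):
            raise InvalidInputError("class counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def default_specs() -> dict[int, RhythmSpec]:
    """Per-class beat statistics (keys are the labels 0-5)."""
    return {
        0: RhythmSpec(0, mean_rr=0.8, rr_jitter_sd=0.03),
        1: RhythmSpec(1, mean_rr=0.8, rr_jitter_sd=0.03,
                      ectopic_probability=0.15, ectopic_prematurity=0.35,
                      ectopic_amplitude_scale=1.4, ectopic_width_scale=1.5,
                      compensatory_pause=True),
        2: RhythmSpec(2, mean_rr=0.8, rr_jitter_sd=0.03,
                      ectopic_probability=0.15, ectopic_prematurity=0.30,
                      ectopic_amplitude_scale=0.8),
        3: RhythmSpec(3, mean_rr=0.35, rr_jitter_sd=0.02,
                      beat_amplitude_scale=0.6, beat_width_scale=1.6),
        4: RhythmSpec(4, mean_rr=0.35, rr_jitter_sd=0.02),
        5: RhythmSpec(5, mean_rr=0.8, rr_jitter_sd=0.20),
    }


def generate_beat_train(spec: RhythmSpec, duration: float = 10.0,
                        rng: Optional[np.random.Generator] = None,
                        seed: Optional[int] = None) -> BeatTrain:
    """Draw one beat train from a rhythm spec.

    RR intervals come from a normal(mean_rr, rr_jitter_sd) floored at
    0.25 s. With probability ``ectopic_probability`` a beat is ectopic: it
    arrives early by ``ectopic_prematurity x RR`` with the spec's ectopic
    amplitude/width multipliers, and with ``compensatory_pause`` the next
    interval is stretched to restore the underlying phase.
    """
    if rng is None:
        rng = np.random.default_rng(seed)

    def draw_rr() -> float:
        return max(RR_FLOOR, rng.normal(spec.mean_rr, spec.rr_jitter_sd))

    times: list[float] = []
    amps: list[float] = []
    widths: list[float] = []
    t = rng.uniform(0.05, 0.05 + spec.mean_rr / 2)
    pending_pause = 0.0
    while t < duration:
        is_ectopic = (spec.ectopic_probability > 0
                      and rng.random() < spec.ectopic_probability)
        amp = spec.beat_amplitude_scale * max(0.1, rng.normal(1.0, AMPLITUDE_JITTER_SD))
        width = spec.beat_width_scale
        if is_ectopic:
            amp *= spec.ectopic_amplitude_scale
            width *= spec.ectopic_width_scale
        times.append(t)
        amps.append(amp)
        widths.append(width)
        rr = draw_rr()
        step = rr + pending_pause
        pending_pause = 0.0
        if is_ectopic:
            advance = spec.ectopic_prematurity * rr
            step = max(RR_FLOOR, rr - advance)
            if spec.compensatory_pause:
                pending_pause = advance
        t += step
    return BeatTrain(np.array(times), np.array(amps), np.array(widths), duration)


def render(train: BeatTrain, cfg: SimConfig,
           rng: Optional[np.random.Generator] = None,
           label: Optional[int] = None) -> PPGSegment:
    """Render a beat train to a PPG waveform of exactly duration x fs samples.

    Each beat contributes a systolic Gaussian and a delayed dicrotic
    Gaussian; white noise and sinusoidal baseline wander are added on top
    (both skipped when their amplitude is zero, keeping rendering
    deterministic and additive over beats).
    """
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    x = np.zeros(n)
    for tb, amp, width in zip(train.beat_times, train.amplitudes, train.widths):
        sigma = SYSTOLIC_SIGMA * width
        x += amp * np.exp(-0.5 * ((t - tb) / sigma) ** 2)
        x += (DICROTIC_AMPLITUDE * amp
              * np.exp(-0.5 * ((t - tb - DICROTIC_DELAY) / sigma) ** 2))
    if cfg.wander_amplitude > 0 or cfg.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        if cfg.wander_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            x += cfg.wander_amplitude * np.sin(
                2 * np.pi * cfg.wander_frequency * t + phase)
        if cfg.noise_sd > 0:
            x += rng.normal(0.0, cfg.noise_sd, n)
    return PPGSegment(x, fs=cfg.fs, label=label)


def generate_dataset(cfg: Optional[SimConfig] = None,
                     specs: Optional[dict[int, RhythmSpec]] = None
                     ) -> LabeledDataset:
    """Generate a labeled dataset with the configured per-class counts.

    Every segment draws its generator from ``SeedSequence([seed, class,
    index])``, so datasets are bit-reproducible and individual segments can
    be regenerated in isolation.
    """
    cfg = cfg or SimConfig()
    specs = specs or default_specs()
    rows: list[np.ndarray] = []
    labels: list[int] = []
    for c, count in enumerate(cfg.class_counts):
        if count == 0:
            continue
        spec = specs[c]
        for i in range(count):
            rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, c, i]))
            train = generate_beat_train(spec, cfg.duration, rng=rng)
            seg = render(train, cfg, rng=rng, label=c)
            rows.append(seg.samples)
            labels.append(c)
    if not rows:
        raise InvalidInputError("all class counts are zero")
    return LabeledDataset(np.vstack(rows), np.array(labels), fs=cfg.fs)


# ---------------------------------------------------------------------------
# A deliberately simple rate/variability rule classifier. It detects beats
# by peak picking and groups segments into {SR-like} / {tachycardic} /
# {AF-like}; it exists to certify that the simulated classes are separable
# by their intended features before any network is trained on them.

def rr_features(samples: np.ndarray, fs: float = 100.0
                ) -> tuple[float, float]:
    """(heart rate in bpm, RR coefficient of variation) via peak detection.

    Baseline wander is removed with a 1-s moving average before peak
    picking; the dicrotic wave (0.25 s after systole) is suppressed by the
    minimum peak distance of 0.3 s, still short enough to keep consecutive
    tachycardic beats (mean RR 0.35 s) apart.
    """
    x = np.asarray(samples, dtype=float)
    w = int(fs)  # 1 s moving average as a crude detrend
    kernel = np.ones(w) / w
    detrended = x - np.convolve(x, kernel, mode="same")
    peaks, _ = find_peaks(detrended, distance=int(0.3 * fs), prominence=0.2)
    duration = len(x) / fs
    rate = len(peaks) / duration * 60.0
    if len(peaks) < 3:
        return rate, 0.0
    rr = np.diff(peaks) / fs
    cv = float(np.std(rr) / np.mean(rr)) if np.mean(rr) > 0 else 0.0
    return rate, cv


def rate_variability_rule(segments: np.ndarray, fs: float = 100.0,
                          tachy_bpm: float = 120.0, af_cv: float = 0.15
                          ) -> np.ndarray:
    """Group segments into 0 = SR-like, 1 = tachycardic, 2 = AF-like."""
    out = np.empty(len(segments), dtype=int)
    for i, row in enumerate(np.atleast_2d(segments)):
        rate, cv = rr_features(row, fs)
        if rate > tachy_bpm:
            out[i] = 1
        elif cv > af_cv:
            out[i] = 2
        else:
            out[i] = 0
    return out
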