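"""Raw EEG segments -> the model's spectral input tensor.

Pipeline: resample to a uniform rate (Fourier-domain resampling), slide a
non-overlapping 1-s window over each clip, take the log-amplitude of the
non-negative FFT bins of each window (DC dropped, bins 1..C kept), and
z-normalize per (channel, feature) element against statistics fitted on the
training split only.  A clip is labeled ictal when its seizure intervals
overlap it by at least 1 s in total (intervals are half-open ``[start,
stop)`` seconds relative to clip start; overlap is summed across intervals
before the threshold test).

At 200 Hz a 1-s window has 101 non-negative bins; dropping the
montage-dependent DC offset leaves the C = 100 spectral features per channel
per second, so a 12-s, 22-channel clip becomes an X of shape 22 x 100 x 12.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

LOG_EPS = 1e-8
SD_FLOOR = 1e-6

logger = logging.getLogger(__name__)

__all__ = [
    "EEGClip", "FeatureTensor", "NormalizationStats",
    "resample", "fft_log_features", "featurize_clip", "label_clip",
    "fit_normalization", "apply_normalization",
]


@dataclass
class EEGClip:
    """A raw multi-channel segment with its seizure annotations."""

    samples: np.ndarray                       # (n_channels, n_samples)
    sample_rate: float
    channel_names: tuple[str, ...]
    seizure_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError("row count does not match channel_names")
        for start, stop in self.seizure_intervals:
            if not start < stop:
                raise ValueError(f"empty interval ({start}, {stop})")
            if start < 0 or stop > self.clip_seconds + 1e-9:
                raise ValueError("interval outside the clip")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def clip_seconds(self) -> float:
        return self.samples.shape[1] / self.sample_rate


@dataclass
class FeatureTensor:
    """Spectral tensor X (channels x features x time-steps) plus its label."""

    X: np.ndarray
    label: int

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 3:
            raise ValueError("X must be 3-D (N x C x T)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains NaN or Inf")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.X.shape


@dataclass
class NormalizationStats:
    """Per-(channel, feature) mean and sd of the training split."""

    mean: np.ndarray            # (N, C, 1)
    sd: np.ndarray              # (N, C, 1), floored strictly positive
    n_training_clips: int


def resample(clip: EEGClip, target_rate: float) -> EEGClip:
    """Fourier-domain resampling to ``target_rate``; duration preserved."""
    if clip.samples.shape[1] == 0:
        raise ValueError("cannot resample a zero-length signal")
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if abs(target_rate - clip.sample_rate) < 1e-12:
        return clip
    n_out = int(round(clip.samples.shape[1] * target_rate / clip.sample_rate))
    out = sp_signal.resample(clip.samples, n_out, axis=1)
    return EEGClip(samples=out, sample_rate=target_rate,
                   channel_names=clip.channel_names,
                   seizure_intervals=list(clip.seizure_intervals))


def fft_log_features(window: np.ndarray, sample_rate: float,
                     n_features: int = 100) -> np.ndarray:
    """log(|FFT| + eps) of the non-negative bins of a 1-s window.

    The DC bin is dropped; bins ``1..n_features`` are kept, so feature index
    ``k`` corresponds to ``k + 1`` cycles per window (``k + 1`` Hz for the
    1-s windows used throughout).
    """
    window = np.asarray(window, dtype=np.float64)
    expected = int(round(sample_rate))
    if window.ndim != 1 or window.size != expected:
        raise ValueError(
            f"window must be 1-D with {expected} samples, got {window.shape}")
    n_bins = expected // 2 + 1
    if not 1 <= n_features <= n_bins - 1:
        raise ValueError(f"n_features must be in [1, {n_bins - 1}]")
    amp = np.abs(np.fft.rfft(window))
    return np.log(amp[1:1 + n_features] + LOG_EPS)


def featurize_clip(clip: EEGClip, n_features: int = 100) -> FeatureTensor:
    """Non-overlapping 1-s windows -> X[n, :, t] = spectral features.

    The clip must contain an integer number of 1-s windows.
    """
    fs = int(round(clip.sample_rate))
    n_samp = clip.samples.shape[1]
    if n_samp % fs != 0:
        raise ValueError("clip duration is not an integer number of seconds")
    T = n_samp // fs
    windows = clip.samples.reshape(clip.n_channels, T, fs)
    amp = np.abs(np.fft.rfft(windows, axis=-1))
    X = np.log(amp[:, :, 1:1 + n_features] + LOG_EPS)  # (N, T, C)
    label = label_clip(clip.seizure_intervals, clip.clip_seconds)
    return FeatureTensor(X=X.transpose(0, 2, 1), label=label)


def label_clip(seizure_intervals: list[tuple[float, float]],
               clip_seconds: float) -> int:
    """1 iff total seizure overlap with the clip is >= 1.0 s (summed)."""
    total = 0.0
    for start, stop in seizure_intervals:
        total += max(0.0, min(stop, clip_seconds) - max(start, 0.0))
    return int(total >= 1.0)


def fit_normalization(train_tensors: list[FeatureTensor]) -> NormalizationStats:
    """Per-(channel, feature) mean/sd over the training clips and time steps.

    Zero-variance elements are floored at ``SD_FLOOR`` with a warning, so
    constant features z-score to 0 rather than NaN.  Fit this on the training
    split only; the interface takes nothing else.
    """
    if len(train_tensors) < 2:
        raise ValueError("need at least 2 training tensors")
    stacked = np.stack([ft.X for ft in train_tensors])       # (B, N, C, T)
    mean = stacked.mean(axis=(0, 3))[:, :, None]
    sd = stacked.std(axis=(0, 3))[:, :, None]
    n_floored = int((sd < SD_FLOOR).sum())
    if n_floored:
        msg = f"{n_floored} zero-variance (channel, feature) elements floored"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    sd = np.maximum(sd, SD_FLOOR)
    return NormalizationStats(mean=mean, sd=sd,
                              n_training_clips=len(train_tensors))


def apply_normalization(ft: FeatureTensor,
                        stats: NormalizationStats) -> FeatureTensor:
    """z-score a tensor with (training-split) statistics."""
    return FeatureTensor(X=(ft.X - stats.mean) / stats.sd, label=ft.label)
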