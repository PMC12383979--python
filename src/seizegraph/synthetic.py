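"""Synthetic multi-channel EEG with planted ictal spatiotemporal structure.

Interictal background is 1/f ("pink") noise per channel plus white sensor
noise, the standard first-order model of resting scalp EEG spectra.  Ictal
clips superpose, on a fixed subset of channels, an amplitude-modulated
spike-wave-like rhythm at ``ictal_freq`` (default 3 Hz, the classic
generalized spike-and-wave rate) with two decaying harmonics, ramped on and
off over 0.5 s and with onsets jittered across channels by up to 0.5 s to
emulate spread.  The burst always overlaps the clip by at least 1 s, so the
clip-labeling rule used downstream (ictal iff >= 1 s of seizure activity)
fires consistently.

Everything is driven by one integer seed and reproduces bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import TUSZ_CHANNELS

__all__ = ["SyntheticSpec", "SyntheticClip", "generate_clips"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for one batch of labeled clips."""

    n_channels: int = 22
    sample_rate: float = 200.0          # Hz
    clip_seconds: float = 12.0
    n_clips: int = 100
    seizure_prevalence: float = 0.05    # fraction of clips labeled ictal
    seizure_channel_subset: tuple[int, ...] = (0, 1, 2, 3, 8, 9)
    ictal_freq: float = 3.0             # Hz, spike-wave-like
    background_exponent: float = 1.0    # spectral slope of 1/f^a background
    background_amp: float = 1.0         # RMS of the background, signal units
    ictal_amp: float = 3.0              # burst amplitude relative to background RMS
    noise_sd: float = 0.3               # white sensor noise, signal units
    seed: int = 0
    channel_names: tuple[str, ...] = field(default=TUSZ_CHANNELS)

    def __post_init__(self):
        if not 0.0 < self.seizure_prevalence < 1.0:
            raise ValueError("seizure_prevalence must lie strictly in (0, 1)")
        if not set(self.seizure_channel_subset) <= set(range(self.n_channels)):
            raise ValueError("seizure_channel_subset outside channel range")
        if len(self.seizure_channel_subset) == 0:
            raise ValueError("seizure_channel_subset must be non-empty")
        n = self.sample_rate * self.clip_seconds
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sample_rate * clip_seconds must be an integer")
        if self.n_channels != len(self.channel_names):
            object.__setattr__(self, "channel_names",
                               tuple(f"CH{i}" for i in range(self.n_channels)))

    @property
    def n_samples(self) -> int:
        return int(round(self.sample_rate * self.clip_seconds))


@dataclass
class SyntheticClip:
    """One generated segment: raw samples, seizure intervals, binary label."""

    samples: np.ndarray                     # (n_channels, n_samples)
    seizure_intervals: list[tuple[float, float]]
    label: int
    sample_rate: float
    channel_names: tuple[str, ...]


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                exponent: float, rms: float) -> np.ndarray:
    """1/f^a noise via spectral shaping of white Gaussian noise."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    scale = shaped.std(axis=-1, keepdims=True)
    scale[scale == 0] = 1.0
    return rms * shaped / scale


def _ictal_burst(t: np.ndarray, onset: float, duration: float, freq: float,
                 amp: float, phase: float) -> np.ndarray:
    """Ramped spike-wave-like rhythm: fundamental plus two decaying harmonics."""
    ramp = 0.5
    env = np.clip((t - onset) / ramp, 0.0, 1.0) * np.clip(
        (onset + duration - t) / ramp, 0.0, 1.0)
    env = np.minimum(env, 1.0)
    wave = (np.sin(2 * np.pi * freq * t + phase)
            + 0.5 * np.sin(2 * np.pi * 2 * freq * t + 2 * phase)
            + 0.25 * np.sin(2 * np.pi * 3 * freq * t + 3 * phase))
    return amp * env * wave


def generate_clips(spec: SyntheticSpec) -> list[SyntheticClip]:
    """Generate ``spec.n_clips`` labeled clips (seeded, reproducible).

    Ictal/interictal assignment is i.i.d. Bernoulli(``seizure_prevalence``);
    each ictal clip carries one burst of 2 s up to the clip length (capped at
    10 s), onset uniform within the clip, per-channel onset jitter <= 0.5 s
    truncated to the clip so every seizure channel keeps >= 1 s of rhythm.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    t = np.arange(n) / spec.sample_rate
    clips: list[SyntheticClip] = []
    subset = np.asarray(spec.seizure_channel_subset, dtype=int)
    max_dur = min(spec.clip_seconds, 10.0)
    min_dur = min(2.0, max_dur)
    for _ in range(spec.n_clips):
        x = _pink_noise(rng, spec.n_channels, n, spec.background_exponent,
                        spec.background_amp)
        x += spec.noise_sd * rng.standard_normal((spec.n_channels, n))
        is_ictal = rng.random() < spec.seizure_prevalence
        intervals: list[tuple[float, float]] = []
        if is_ictal:
            duration = rng.uniform(min_dur, max_dur)
            start = rng.uniform(0.0, spec.clip_seconds - duration)
            phase = rng.uniform(0.0, 2 * np.pi)
            amp = spec.ictal_amp * spec.background_amp
            for ch in subset:
                jitter = rng.uniform(0.0, 0.5)
                onset = min(start + jitter, spec.clip_seconds - 1.0)
                x[ch] += _ictal_burst(t, onset, duration, spec.ictal_freq,
                                      amp, phase)
            intervals.append((float(start), float(min(start + duration + 0.5,
                                                      spec.clip_seconds))))
        label = int(sum(b - a for a, b in intervals) >= 1.0)
        clips.append(SyntheticClip(samples=x, seizure_intervals=intervals,
                                   label=label, sample_rate=spec.sample_rate,
                                   channel_names=spec.channel_names))
    return clips
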