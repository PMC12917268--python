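"""Seed-controlled synthetic EEG generator.

Emulates the two regimes a seizure detector must separate: interictal
background, modelled as Gaussian noise shaped to a 1/f^beta power
spectrum (the standard surrogate for resting scalp EEG), and ictal
segments, modelled as an amplitude-modulated rhythmic burst in a low
theta-range band riding on the same background with an amplitude gain
greater than one.  Labels mark exactly the segments that received a
burst, so every downstream stage is testable without any recording.

The default class balance (19.4% ictal) mirrors the focal/non-focal
proportion of the CHB-MIT scalp-EEG corpus; sampling rate defaults to
the corpus's 256 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .record import EEGRecord

__all__ = ["GeneratorConfig", "generate_record", "generate_dataset"]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic EEG world.

    Attributes
    ----------
    fs : float
        Sampling rate, Hz.
    duration : float
        Record length, seconds.
    n_channels : int
        Number of channels.
    segment_length : int
        Samples per labelled segment.
    ictal_fraction : float
        Bernoulli probability that a segment is ictal.
    background_beta : float
        Exponent of the 1/f^beta background power spectrum.
    background_scale : float
        RMS amplitude of the background, microvolts.
    ictal_band : tuple of float
        (low, high) Hz band the rhythmic burst frequency is drawn from.
    ictal_gain : float
        Burst peak amplitude as a multiple of the background RMS; > 1.
    seed : int
        Master seed; identical config + seed reproduces samples exactly.
    """

    fs: float = 256.0
    duration: float = 60.0
    n_channels: int = 1
    segment_length: int = 2000
    ictal_fraction: float = 0.194
    background_beta: float = 1.0
    background_scale: float = 20.0
    ictal_band: tuple[float, float] = (3.0, 8.0)
    ictal_gain: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if not 0.0 <= self.ictal_fraction <= 1.0:
            raise ValueError("ictal_fraction must lie in [0, 1]")
        if self.ictal_fraction > 0 and self.ictal_gain <= 1.0:
            raise ValueError("ictal amplitude gain must exceed 1")
        if not 0 < self.ictal_band[0] < self.ictal_band[1] < self.fs / 2:
            raise ValueError("ictal_band must satisfy 0 < low < high < fs/2")


def _pink_noise(rng: np.random.Generator, n: int, beta: float, scale: float) -> np.ndarray:
    """Gaussian noise shaped to a 1/f^beta power spectrum, RMS-normalised to scale."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    # amplitude shaping 1/f^(beta/2) gives power 1/f^beta; DC stays zero
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spectrum * shape, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x * (scale / rms) if rms > 0 else x


def generate_record(config: GeneratorConfig) -> EEGRecord:
    """Generate one labelled synthetic EEG record.

    Each segment is drawn ictal with probability ``config.ictal_fraction``;
    ictal segments receive, on every channel, a Hann-enveloped sinusoid at
    a frequency sampled uniformly from ``ictal_band`` with peak amplitude
    ``ictal_gain * background_scale`` and a random phase.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = int(round(config.duration * config.fs))
    n_segments = n_samples // config.segment_length

    signal = np.empty((config.n_channels, n_samples))
    for ch in range(config.n_channels):
        signal[ch] = _pink_noise(rng, n_samples, config.background_beta, config.background_scale)

    labels = (rng.random(n_segments) < config.ictal_fraction).astype(np.int64)

    t = np.arange(config.segment_length) / config.fs
    envelope = np.hanning(config.segment_length)
    amplitude = config.ictal_gain * config.background_scale
    low, high = config.ictal_band
    for seg in np.flatnonzero(labels):
        start = seg * config.segment_length
        for ch in range(config.n_channels):
            freq = rng.uniform(low, high)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            burst = amplitude * envelope * np.sin(2.0 * np.pi * freq * t + phase)
            signal[ch, start : start + config.segment_length] += burst

    return EEGRecord(
        signal=signal,
        fs=config.fs,
        channel_names=[f"EEG{ch + 1}" for ch in range(config.n_channels)],
        segment_labels=labels,
        segment_length=config.segment_length,
    )


def generate_dataset(n_records: int, config: GeneratorConfig) -> list[EEGRecord]:
    """Generate independent records with per-record seeds master_seed + index."""
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    records = []
    for i in range(n_records):
        cfg = GeneratorConfig(**{**config.__dict__, "seed": config.seed + i})
        records.append(generate_record(cfg))
    return records
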