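"""Multichannel EEG record container.

The record is the unit every pipeline stage consumes and produces: a
``(n_channels, n_samples)`` float array of amplitudes in microvolts, a
sampling rate, channel names, and one binary label per fixed-length
segment (1 = ictal, 0 = interictal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EEGRecord:
    """Multichannel sampled EEG with per-segment binary labels.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz (256 for scalp-EEG corpora of the CHB-MIT kind).
    channel_names : list of str
        One identifier per channel.
    segment_labels : ndarray of {0, 1}
        One label per consecutive non-overlapping window of
        ``segment_length`` samples; 1 marks an ictal (seizure) segment.
    segment_length : int
        Window length in samples that the labels refer to.
    """

    signal: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    segment_labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    segment_length: int = 2000

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim == 1:
            self.signal = self.signal[None, :]
        if self.signal.ndim != 2:
            raise ValueError("signal must be (n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match signal rows")
        self.segment_labels = np.asarray(self.segment_labels, dtype=np.int64)
        expected = self.n_samples // self.segment_length
        if self.segment_labels.size and self.segment_labels.size != expected:
            raise ValueError(
                f"expected {expected} segment labels for {self.n_samples} samples "
                f"at segment_length {self.segment_length}, got {self.segment_labels.size}"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    @property
    def n_segments(self) -> int:
        return self.n_samples // self.segment_length

    def with_signal(self, signal: np.ndarray) -> "EEGRecord":
        """Copy of this record with the samples replaced (labels untouched)."""
        return EEGRecord(
            signal=np.asarray(signal, dtype=np.float64),
            fs=self.fs,
            channel_names=list(self.channel_names),
            segment_labels=self.segment_labels.copy(),
            segment_length=self.segment_length,
        )
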