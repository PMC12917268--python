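"""Statistical frequency-state (StFS) feature extraction.

Each fixed-length EEG segment is summarised by 13 features drawn from
three families:

* statistical (5): skewness, kurtosis, mean, median, standard deviation
  of the raw amplitudes, with population-normalised central moments
  (sigma = sqrt(m2), skewness = m3/sigma^3, kurtosis = m4/sigma^4);
* Hjorth (3): activity (variance), mobility (sqrt of the variance ratio
  of the first difference to the signal), complexity (mobility of the
  first difference over mobility of the signal);
* spectral (5): centroid, spread, kurtosis, skewness and crest factor of
  the one-sided Hann periodogram restricted to the analysis band.

The concatenated vector is ordered (spectral, Hjorth, statistical).
Degenerate constant segments are flagged and their moment-based entries
zeroed by convention rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .record import EEGRecord

__all__ = [
    "Segment",
    "Spectrum",
    "StFSVector",
    "FEATURE_NAMES",
    "FEATURE_FAMILIES",
    "segment_signal",
    "statistical_features",
    "hjorth_features",
    "power_spectrum",
    "spectral_features",
    "extract_stfs",
    "features_table",
]

FEATURE_NAMES = [
    "spectral_centroid",
    "spectral_spread",
    "spectral_kurtosis",
    "spectral_skewness",
    "spectral_crest",
    "hjorth_activity",
    "hjorth_mobility",
    "hjorth_complexity",
    "stat_skewness",
    "stat_kurtosis",
    "stat_mean",
    "stat_median",
    "stat_std",
]

FEATURE_FAMILIES = {
    "spectral": FEATURE_NAMES[0:5],
    "hjorth": FEATURE_NAMES[5:8],
    "statistical": FEATURE_NAMES[8:13],
}

#: analysis band (Hz) matching the preprocessing passband
DEFAULT_BAND = (0.05, 75.0)


@dataclass
class Segment:
    """One fixed-length window of a single channel with its label."""

    samples: np.ndarray
    fs: float
    channel: int = 0
    label: int = 0
    index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.samples.size < 8:
            raise ValueError("segments must hold at least 8 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("segment contains non-finite samples")


@dataclass
class Spectrum:
    """One-sided power spectrum restricted to a band [j1, j2]."""

    frequencies: np.ndarray
    power: np.ndarray
    band: tuple[float, float] = DEFAULT_BAND

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequency and power arrays must align")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power values must be non-negative")
        if not self.band[0] < self.band[1]:
            raise ValueError("band must satisfy j1 < j2")


@dataclass
class StFSVector:
    """13 concatenated features, ordered (spectral, Hjorth, statistical)."""

    spectral: np.ndarray
    hjorth: np.ndarray
    statistical: np.ndarray
    degenerate: bool = False
    label: int = 0

    @property
    def values(self) -> np.ndarray:
        v = np.concatenate([self.spectral, self.hjorth, self.statistical])
        assert v.size == 13
        return v


def segment_signal(
    record: EEGRecord, length: int | None = None, overlap: int = 0
) -> list[Segment]:
    """Split every channel into windows of ``length`` samples.

    Windows advance by ``length - overlap`` samples; the trailing partial
    window is dropped.  Each window inherits the label of the fixed
    labelling grid cell its start sample falls in.
    """
    length = length or record.segment_length
    if length > record.n_samples:
        raise ValueError(f"segment length {length} exceeds record length {record.n_samples}")
    if not 0 <= overlap < length:
        raise ValueError("overlap must satisfy 0 <= overlap < length")
    step = length - overlap
    segments = []
    for ch in range(record.n_channels):
        for idx, start in enumerate(range(0, record.n_samples - length + 1, step)):
            if record.segment_labels.size:
                cell = min(start // record.segment_length, record.segment_labels.size - 1)
                label = int(record.segment_labels[cell])
            else:
                label = 0
            segments.append(
                Segment(
                    samples=record.signal[ch, start : start + length],
                    fs=record.fs,
                    channel=ch,
                    label=label,
                    index=idx,
                )
            )
    return segments


def _samples(seg) -> np.ndarray:
    return seg.samples if isinstance(seg, Segment) else np.asarray(seg, dtype=np.float64).ravel()


def statistical_features(seg: Segment | np.ndarray) -> np.ndarray:
    """[skewness, kurtosis, mean, median, std] with population moments.

    Accepts a :class:`Segment` or a plain sample array.  A constant
    segment has undefined moment ratios; skewness and kurtosis are set
    to 0 by convention there (the caller flags the vector).
    """
    u = _samples(seg)
    if u.size < 2:
        raise ValueError("need at least 2 samples")
    mean = u.mean()
    centered = u - mean
    m2 = np.mean(centered**2)
    std = np.sqrt(m2)
    median = float(np.median(u))
    if std > 0:
        skew = np.mean(centered**3) / std**3
        kurt = np.mean(centered**4) / std**4
    else:
        skew = kurt = 0.0
    return np.array([skew, kurt, mean, median, std])


def hjorth_features(seg: Segment | np.ndarray) -> np.ndarray:
    """Hjorth (activity, mobility, complexity) via first differences.

    activity = var(U); mobility = sqrt(var(dU)/var(U));
    complexity = mobility(dU)/mobility(U).  Accepts a :class:`Segment`
    or a plain sample array; a constant signal returns (0, 0, 0) by
    convention.
    """
    u = _samples(seg)
    var0 = np.var(u)
    if var0 == 0:
        return np.zeros(3)
    d1 = np.diff(u)
    d2 = np.diff(d1)
    var1 = np.var(d1)
    var2 = np.var(d2)
    mobility = np.sqrt(var1 / var0)
    mobility_d = np.sqrt(var2 / var1) if var1 > 0 else 0.0
    complexity = mobility_d / mobility if mobility > 0 else 0.0
    return np.array([var0, mobility, complexity])


def power_spectrum(seg: Segment, band: tuple[float, float] = DEFAULT_BAND) -> Spectrum:
    """One-sided Hann periodogram restricted to ``band`` (the passband)."""
    freqs, power = sps.periodogram(seg.samples, fs=seg.fs, window="hann", detrend="constant")
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(keep):
        raise ValueError("analysis band contains no spectral bins")
    return Spectrum(frequencies=freqs[keep], power=power[keep], band=band)


def spectral_features(sp: Spectrum) -> np.ndarray:
    """[centroid, spread, kurtosis, skewness, crest] of a band spectrum.

    Moments are power-weighted frequency moments; crest is the peak power
    over the band-mean power (>= 1 for any non-zero spectrum).  A point
    mass has zero spread, where standardised skewness/kurtosis are
    undefined and returned as 0.
    """
    f, p = sp.frequencies, sp.power
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum: spectral features undefined")
    centroid = float((f * p).sum() / total)
    dev = f - centroid
    spread = float(np.sqrt((dev**2 * p).sum() / total))
    if spread > 0:
        skew = float((dev**3 * p).sum() / (spread**3 * total))
        kurt = float((dev**4 * p).sum() / (spread**4 * total))
    else:
        skew = kurt = 0.0
    crest = float(p.max() / p.mean())
    return np.array([centroid, spread, kurt, skew, crest])


def extract_stfs(seg: Segment, band: tuple[float, float] = DEFAULT_BAND) -> StFSVector:
    """Full 13-feature vector for one segment.

    Constant segments cannot support moment or spectral features; they
    yield a flagged vector whose moment entries are zero while mean,
    median and std stay meaningful.
    """
    stat = statistical_features(seg)
    if np.ptp(seg.samples) == 0:
        return StFSVector(
            spectral=np.zeros(5),
            hjorth=np.zeros(3),
            statistical=stat,
            degenerate=True,
            label=seg.label,
        )
    return StFSVector(
        spectral=spectral_features(power_spectrum(seg, band)),
        hjorth=hjorth_features(seg),
        statistical=stat,
        degenerate=False,
        label=seg.label,
    )


def features_table(
    record: EEGRecord,
    length: int | None = None,
    overlap: int = 0,
    band: tuple[float, float] = DEFAULT_BAND,
    average_channels: bool = True,
):
    """Per-segment feature table as a pandas DataFrame.

    Columns: ``segment_id``, ``channel`` (−1 once averaged), the 13 named
    features, ``label``.  Multichannel records are reduced by averaging
    each feature across channels within a segment, keeping one row and
    one label per time window.
    """
    import pandas as pd

    rows = []
    for seg in segment_signal(record, length=length, overlap=overlap):
        vec = extract_stfs(seg, band=band)
        rows.append(
            {"segment_id": seg.index, "channel": seg.channel, "label": seg.label}
            | dict(zip(FEATURE_NAMES, vec.values))
        )
    df = pd.DataFrame(rows, columns=["segment_id", "channel", *FEATURE_NAMES, "label"])
    if average_channels and not df.empty:
        grouped = df.groupby("segment_id", sort=True)
        out = grouped[FEATURE_NAMES].mean().reset_index()
        out.insert(1, "channel", -1)
        out["label"] = grouped["label"].first().to_numpy()
        return out
    return df
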