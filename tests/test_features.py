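"""StFS feature extraction: oracles, invariants, degenerate contracts."""

import numpy as np
import pytest

from seizeeg import EEGRecord, GeneratorConfig, generate_record, segment_signal
from seizeeg.features import (
    FEATURE_FAMILIES,
    FEATURE_NAMES,
    Segment,
    Spectrum,
    extract_stfs,
    hjorth_features,
    power_spectrum,
    spectral_features,
    statistical_features,
)

FS = 256.0


def _segment(x, fs=FS, label=0):
    return Segment(samples=np.asarray(x, dtype=float), fs=fs, label=label)


class TestSegmentation:
    @pytest.mark.parametrize(
        "n_samples, length, overlap, expected",
        [
            (10000, 2000, 0, 5),
            (1999, 2000, 0, None),  # shorter than one window -> error per contract
            (6000, 2000, 1000, 5),  # starts 0,1000,2000,3000,4000
            (4000, 2000, 0, 2),
        ],
    )
    def test_window_counts(self, n_samples, length, overlap, expected):
        rec = EEGRecord(signal=np.zeros((1, n_samples)), fs=FS, segment_length=length)
        if expected is None:
            with pytest.raises(ValueError):
                segment_signal(rec, length=length, overlap=overlap)
        else:
            assert len(segment_signal(rec, length=length, overlap=overlap)) == expected

    def test_partial_trailing_window_dropped(self):
        rec = EEGRecord(signal=np.zeros((1, 4500)), fs=FS, segment_length=2000)
        assert len(segment_signal(rec, length=2000)) == 2

    def test_segments_inherit_labels(self):
        rec = EEGRecord(
            signal=np.zeros((1, 6000)), fs=FS, segment_labels=[1, 0, 1], segment_length=2000
        )
        assert [s.label for s in segment_signal(rec)] == [1, 0, 1]


class TestStatistical:
    def test_small_vector_oracle(self):
        """Direct evaluation of the population formulas on U = [1, 2, 3]."""
        skew, kurt, mean, median, std = statistical_features(np.array([1.0, 2.0, 3.0]))
        assert mean == 2.0
        assert median == 2.0
        assert std == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-12)
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_segment_has_zero_skewness(self):
        skew = statistical_features(np.array([-1.0, 0.0, 1.0]))[0]
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_kurtosis_is_three(self, rng):
        """10^6 standard-normal samples: m4/sigma^4 -> 3 (Gaussian closed form)."""
        kurt = statistical_features(rng.standard_normal(10**6))[1]
        assert kurt == pytest.approx(3.0, abs=0.05)

    def test_constant_segment_moments_zeroed(self):
        skew, kurt, mean, median, std = statistical_features(np.full(100, 7.0))
        assert (skew, kurt, std) == (0.0, 0.0, 0.0)
        assert mean == median == 7.0


class TestHjorth:
    def test_constant_signal_is_all_zero(self):
        np.testing.assert_array_equal(hjorth_features(np.full(100, 3.0)), np.zeros(3))

    def test_alternating_signal(self):
        """U = [0,1,0,1,...]: var = 0.25 and the first differences alternate
        +-1, so activity = 0.25 and mobility ~ 2."""
        u = np.tile([0.0, 1.0], 1000)
        activity, mobility, _ = hjorth_features(u)
        assert activity == pytest.approx(0.25, abs=1e-12)
        assert mobility == pytest.approx(2.0, rel=1e-5)

    def test_sinusoid_complexity_near_one(self):
        """A pure tone's derivative is a tone of the same frequency, so
        complexity (mobility ratio) is ~1."""
        t = np.arange(2000) / FS
        u = np.sin(2 * np.pi * 5.0 * t)
        complexity = hjorth_features(u)[2]
        assert complexity == pytest.approx(1.0, rel=0.02)


def _oracle_periodogram(x, fs):
    """Independent direct-summation Hann periodogram (one-sided, density)."""
    n = len(x)
    xd = x - sum(x) / n
    w = np.array([0.5 - 0.5 * np.cos(2 * np.pi * j / n) for j in range(n)])
    xw = w * xd
    freqs, power = [], []
    for k in range(n // 2 + 1):
        re = sum(xw[j] * np.cos(2 * np.pi * j * k / n) for j in range(n))
        im = -sum(xw[j] * np.sin(2 * np.pi * j * k / n) for j in range(n))
        p = (re**2 + im**2) / (fs * float(np.sum(w**2)))
        if 0 < k < n / 2:
            p *= 2.0
        freqs.append(k * fs / n)
        power.append(p)
    return np.array(freqs), np.array(power)


class TestSpectrum:
    def test_matches_direct_dft_oracle(self, rng):
        x = rng.standard_normal(16)
        sp = power_spectrum(_segment(x), band=(0.0, FS / 2))
        freqs, power = _oracle_periodogram(x, FS)
        np.testing.assert_allclose(sp.frequencies, freqs, atol=1e-12)
        np.testing.assert_allclose(sp.power, power, atol=1e-12)

    def test_parseval_identity(self, rng):
        """Band-integrated power equals the windowed-signal variance
        sum((w * x_detrended)^2) / sum(w^2) within 1%."""
        x = rng.standard_normal(2000)
        sp = power_spectrum(_segment(x), band=(0.0, FS / 2))
        df = sp.frequencies[1] - sp.frequencies[0]
        n = len(x)
        w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / n)
        oracle = np.sum((w * (x - x.mean())) ** 2) / np.sum(w**2)
        assert np.sum(sp.power) * df == pytest.approx(oracle, rel=0.01)

    def test_pure_tone_peaks_at_nearest_bin(self):
        t = np.arange(2000) / FS
        sp = power_spectrum(_segment(np.sin(2 * np.pi * 10.0 * t)))
        peak_freq = sp.frequencies[np.argmax(sp.power)]
        assert abs(peak_freq - 10.0) <= FS / 2000

    def test_white_noise_band_power_roughly_flat(self):
        """Averaged over many draws, low- and high-band mean power agree."""
        rng = np.random.default_rng(77)
        lows, highs = [], []
        for _ in range(50):
            sp = power_spectrum(_segment(rng.standard_normal(2000)))
            lows.append(sp.power[(sp.frequencies >= 5) & (sp.frequencies < 40)].mean())
            highs.append(sp.power[(sp.frequencies >= 40) & (sp.frequencies < 75)].mean())
        ratio = np.mean(lows) / np.mean(highs)
        assert 0.9 < ratio < 1.1


class TestSpectralFeatures:
    def test_point_mass(self):
        """Single nonzero bin at 10 Hz: centroid 10, spread 0, crest = #bins."""
        freqs = np.arange(1.0, 21.0)
        power = np.zeros(20)
        power[9] = 4.0
        centroid, spread, kurt, skew, crest = spectral_features(
            Spectrum(frequencies=freqs, power=power, band=(1.0, 20.0))
        )
        assert centroid == 10.0
        assert spread == 0.0
        assert (kurt, skew) == (0.0, 0.0)
        assert crest == 20.0

    def test_symmetric_spectrum_zero_skewness(self):
        freqs = np.array([5.0, 10.0, 15.0])
        power = np.array([2.0, 3.0, 2.0])
        skew = spectral_features(Spectrum(frequencies=freqs, power=power))[3]
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_bins(self):
        """Bins at 5 and 15 Hz: centroid 10, spread 5, kurtosis 1 by direct
        evaluation of the moment formulas."""
        sp = Spectrum(frequencies=np.array([5.0, 15.0]), power=np.array([1.0, 1.0]))
        centroid, spread, kurt, skew, crest = spectral_features(sp)
        assert centroid == 5.0 * 1 / 2 + 15.0 * 1 / 2
        assert spread == pytest.approx(5.0, abs=1e-12)
        assert kurt == pytest.approx(1.0, abs=1e-12)
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert crest == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_spectrum_rejected(self):
        sp = Spectrum(frequencies=np.array([1.0, 2.0]), power=np.zeros(2))
        with pytest.raises(ValueError, match="all-zero"):
            spectral_features(sp)


class TestExtract:
    def test_families_concatenate_to_13(self, rng):
        vec = extract_stfs(_segment(rng.standard_normal(2000)))
        assert vec.spectral.size == 5
        assert vec.hjorth.size == 3
        assert vec.statistical.size == 5
        assert vec.values.size == 13
        assert np.all(np.isfinite(vec.values))
        assert len(FEATURE_NAMES) == 13
        assert [len(v) for v in FEATURE_FAMILIES.values()] == [5, 3, 5]

    def test_constant_segment_flagged_and_zeroed(self):
        vec = extract_stfs(_segment(np.full(2000, 4.2)))
        assert vec.degenerate
        np.testing.assert_array_equal(vec.spectral, np.zeros(5))
        np.testing.assert_array_equal(vec.hjorth, np.zeros(3))
        assert vec.statistical[2] == pytest.approx(4.2)  # mean survives

    def test_sixteen_sample_brute_force_oracle(self, rng):
        """Every one of the 13 features on a toy segment matches an
        independent direct-summation implementation to 1e-12."""
        x = rng.standard_normal(16)
        vec = extract_stfs(_segment(x), band=(0.0, FS / 2)).values

        n = len(x)
        mean = sum(x) / n
        m2 = sum((v - mean) ** 2 for v in x) / n
        m3 = sum((v - mean) ** 3 for v in x) / n
        m4 = sum((v - mean) ** 4 for v in x) / n
        std = m2**0.5
        stat = [m3 / std**3, m4 / std**4, mean, float(np.median(x)), std]

        d1 = [x[j + 1] - x[j] for j in range(n - 1)]
        d2 = [d1[j + 1] - d1[j] for j in range(n - 2)]

        def var(v):
            mu = sum(v) / len(v)
            return sum((e - mu) ** 2 for e in v) / len(v)

        mob = (var(d1) / var(x)) ** 0.5
        hjorth = [var(x), mob, ((var(d2) / var(d1)) ** 0.5) / mob]

        freqs, power = _oracle_periodogram(x, FS)
        total = sum(power)
        centroid = sum(f * p for f, p in zip(freqs, power)) / total
        spread = (sum((f - centroid) ** 2 * p for f, p in zip(freqs, power)) / total) ** 0.5
        skew = sum((f - centroid) ** 3 * p for f, p in zip(freqs, power)) / (spread**3 * total)
        kurt = sum((f - centroid) ** 4 * p for f, p in zip(freqs, power)) / (spread**4 * total)
        crest = max(power) / (total / len(power))
        spectral = [centroid, spread, kurt, skew, crest]

        np.testing.assert_allclose(vec, np.array(spectral + hjorth + stat), atol=1e-12)

    @pytest.mark.parametrize("c", [0.5, 3.7])
    def test_scale_covariance(self, rng, c):
        """Scaling a segment by c > 0 scales activity by c^2 and std/mean by
        c, and leaves every shape feature unchanged."""
        x = rng.standard_normal(2000)
        base = extract_stfs(_segment(x)).values
        scaled = extract_stfs(_segment(c * x)).values
        named = dict(zip(FEATURE_NAMES, zip(base, scaled)))
        assert named["hjorth_activity"][1] == pytest.approx(
            c**2 * named["hjorth_activity"][0], rel=1e-9
        )
        assert named["stat_std"][1] == pytest.approx(c * named["stat_std"][0], rel=1e-9)
        for invariant in [
            "spectral_centroid",
            "spectral_spread",
            "spectral_kurtosis",
            "spectral_skewness",
            "spectral_crest",
            "hjorth_mobility",
            "hjorth_complexity",
            "stat_skewness",
            "stat_kurtosis",
        ]:
            assert named[invariant][1] == pytest.approx(named[invariant][0], rel=1e-9)

    def test_ictal_activity_exceeds_interictal(self, separable_table):
        """Over 500+ synthetic segments the mean Hjorth activity of the
        ictal class sits strictly above the interictal class's."""
        assert len(separable_table) >= 500
        by_label = separable_table.groupby("label")["hjorth_activity"].mean()
        assert by_label[1] > by_label[0]
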