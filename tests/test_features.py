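import numpy as np
import pytest
from scipy.signal import get_window

from gait2dft import (
    MagnitudeSeries,
    SlabSelection,
    SpectralParams,
    build_high_density_matrix,
    build_low_density_matrix,
    segment_signal,
    short_time_spectrum,
    two_dft,
)
from gait2dft.errors import ParameterError, SelectionError, SizeError


def _series(values, rate=100.0, start=0.0):
    return MagnitudeSeries(start_time=start, rate=rate, values=values)


def brute_force_two_dft(values, params):
    """Independent double-DFT oracle: explicit O(n^2) DFT sums, no FFT."""
    w = params.segment_samples
    hop = params.hop_samples
    starts = range(0, len(values) - w + 1, hop)
    taper = get_window(params.window, w, fftbins=True)
    spect = []
    for s in starts:
        seg = np.asarray(values[s : s + w], dtype=float)
        seg = (seg - seg.mean()) * taper
        row = [
            abs(sum(seg[n] * np.exp(-2j * np.pi * k * n / w) for n in range(w)))
            for k in range(w // 2 + 1)
        ]
        spect.append(row)
    spect = np.array(spect)
    nw = spect.shape[0]
    second = np.empty((nw // 2 + 1, spect.shape[1]))
    for k in range(nw // 2 + 1):
        second[k] = np.abs(
            sum(spect[m] * np.exp(-2j * np.pi * k * m / nw) for m in range(nw))
        )
    return second.T  # (frequency, repetition rate)


class TestSegmentation:
    @pytest.mark.parametrize(
        "n, res, overlap, expected_windows",
        [
            (300, 0.3, 2, 19),  # floor((300-30)/15)+1
            (300, 0.3, 1, 10),  # disjoint
            (300, 3.0, 1, 1),  # degenerate single window
        ],
    )
    def test_window_counts(self, n, res, overlap, expected_windows):
        p = SpectralParams(temporal_resolution=res, overlap_factor=overlap)
        wins = segment_signal(np.arange(n, dtype=float), p)
        assert wins.shape == (expected_windows, p.segment_samples)
        # brute-force re-count
        count = 0
        s = 0
        while s + p.segment_samples <= n:
            count += 1
            s += p.hop_samples
        assert wins.shape[0] == count

    def test_adjacent_windows_share_half_their_samples(self):
        p = SpectralParams()
        x = np.arange(300, dtype=float)
        wins = segment_signal(x, p)
        for a, b in zip(wins[:-1], wins[1:]):
            np.testing.assert_array_equal(a[p.hop_samples :], b[: p.segment_samples - p.hop_samples])
        assert p.segment_samples - p.hop_samples == p.segment_samples // 2

    def test_short_slab_rejected(self):
        with pytest.raises(SizeError):
            segment_signal(np.zeros(10), SpectralParams())

    def test_indivisible_hop_rejected(self):
        with pytest.raises(ParameterError):
            SpectralParams(temporal_resolution=0.3, overlap_factor=7)


class TestShortTimeSpectrum:
    def test_constant_signal_vanishes_after_demeaning(self):
        p = SpectralParams()
        wins = segment_signal(np.ones(300), p)
        np.testing.assert_allclose(short_time_spectrum(wins, p), 0.0, atol=1e-12)

    def test_sinusoid_matches_direct_dft(self):
        p = SpectralParams()
        t = np.arange(300) / p.rate
        x = np.sin(2 * np.pi * 5.0 * t)
        wins = segment_signal(x, p)
        spect = short_time_spectrum(wins, p)
        assert spect.shape == (19, 16)
        assert np.all(spect >= 0)
        taper = get_window(p.window, 30, fftbins=True)
        for i, wvals in enumerate(wins):
            seg = (wvals - wvals.mean()) * taper
            direct = np.abs(
                [sum(seg * np.exp(-2j * np.pi * k * np.arange(30) / 30)) for k in range(16)]
            )
            np.testing.assert_allclose(spect[i], direct, rtol=1e-9, atol=1e-9)
        # a 5 Hz tone falls between bins 1 and 2 of the 3.33 Hz grid
        mean_spectrum = spect.mean(axis=0)
        assert set(np.argsort(mean_spectrum)[-2:]) == {1, 2}


class TestTwoDft:
    def test_am_tone_peak_location_and_oracle(self):
        """10 Hz carrier amplitude-modulated at 2 Hz: peak at (~10 Hz, ~2 c/s)."""
        p = SpectralParams()
        t = np.arange(300) / p.rate
        x = 2.0 + (1.0 + 0.8 * np.cos(2 * np.pi * 2.0 * t)) * np.cos(2 * np.pi * 10.0 * t)
        spec = two_dft(_series(x), p)
        oracle = brute_force_two_dft(x, p)
        np.testing.assert_allclose(spec.matrix, oracle, rtol=1e-9, atol=1e-9)

        m = spec.matrix.copy()
        m[:, 0] = 0.0  # ignore the static repetition-rate column
        fi, ri = np.unravel_index(np.argmax(m), m.shape)
        assert spec.freqs[fi] == pytest.approx(10.0, abs=p.rate / p.segment_samples)
        assert spec.rep_rates[ri] == pytest.approx(2.0, abs=2 * spec.rep_rates[1])

    def test_constant_slab_vanishes(self):
        spec = two_dft(_series(np.full(300, 1.0)), SpectralParams())
        np.testing.assert_allclose(spec.matrix, 0.0, atol=1e-12)

    def test_wrong_duration_rejected(self):
        with pytest.raises(SizeError):
            two_dft(_series(np.ones(250)), SpectralParams())

    def test_feature_vector_is_frequency_major_flattening(self):
        p = SpectralParams()
        rng = np.random.default_rng(0)
        spec = two_dft(_series(rng.random(300) + 1.0), p)
        assert spec.feature_vector.size == spec.matrix.size
        np.testing.assert_array_equal(
            spec.feature_vector[: spec.rep_rates.size], spec.matrix[0]
        )

    def test_linearity_amplitude_doubling(self, rng):
        p = SpectralParams()
        x = rng.standard_normal(300)
        a = two_dft(_series(1.0 + 0.1 * x), p).matrix
        b = two_dft(_series(1.0 + 0.2 * x), p).matrix
        np.testing.assert_allclose(b, 2 * a, rtol=1e-9, atol=1e-9)

    def test_phase_robustness_for_periodic_signal(self):
        """Shifting the slab by one exact gait period changes the feature < 5%."""
        p = SpectralParams()
        period = 0.5  # 2 steps/s -> 50 samples at 100 Hz
        t = np.arange(400) / p.rate
        x = 1.0 + 0.4 * np.cos(2 * np.pi * 2.0 * t) + 0.2 * np.cos(2 * np.pi * 4.0 * t + 1.0)
        f0 = two_dft(_series(x[:300]), p).feature_vector
        f1 = two_dft(_series(x[50:350]), p).feature_vector
        rel = np.linalg.norm(f1 - f0) / np.linalg.norm(f0)
        assert rel < 0.05


class TestFeatureMatrices:
    def _series_and_selections(self, n_per_condition=10, conditions=("slow", "normal", "fast")):
        rng = np.random.default_rng(3)
        series = _series(1.0 + 0.2 * rng.standard_normal(12000))  # 120 s
        sels = [
            SlabSelection(c, start_time=4.0 * (i + len(conditions) * j))
            for j, c in enumerate(conditions)
            for i in range(n_per_condition)
        ]
        return series, sels

    def test_low_density_counts_and_order(self, params):
        series, sels = self._series_and_selections()
        fm = build_low_density_matrix(series, sels, params)
        assert fm.n_rows == 30
        assert fm.density == "low"
        assert list(fm.labels) == sorted(fm.labels, key=str)
        assert np.all(fm.rows >= 0)

    def test_single_selection_single_row(self, params):
        series, _ = self._series_and_selections()
        fm = build_low_density_matrix(series, [SlabSelection("normal", 1.0)], params)
        assert fm.n_rows == 1

    def test_out_of_bounds_selection_named_in_error(self, params):
        series, _ = self._series_and_selections()
        bad = SlabSelection("fast", series.end_time - 0.5)
        with pytest.raises(SelectionError, match="fast"):
            build_low_density_matrix(series, [bad], params)

    def test_high_density_counts(self, params):
        series, sels = self._series_and_selections()
        fm = build_high_density_matrix(series, sels, params)
        assert fm.n_rows == 300
        for c in ("slow", "normal", "fast"):
            assert int((fm.labels == c).sum()) == 100

    def test_single_increment_degenerates_to_low_density(self, params):
        series, sels = self._series_and_selections()
        low = build_low_density_matrix(series, sels, params)
        high = build_high_density_matrix(series, sels, params, increment=0.1, span=0.1)
        np.testing.assert_allclose(high.rows, low.rows)

    def test_partial_span_row_count(self, params):
        series, _ = self._series_and_selections()
        sels = [SlabSelection("normal", 1.0), SlabSelection("normal", 10.0)]
        fm = build_high_density_matrix(series, sels, params, increment=0.1, span=0.5)
        assert fm.n_rows == 10  # 2 selections x 5 shifts

    def test_hdf5_roundtrip(self, tmp_path, params):
        series, sels = self._series_and_selections(n_per_condition=2)
        fm = build_low_density_matrix(series, sels, params)
        path = tmp_path / "fm.h5"
        fm.to_hdf5(path)
        from gait2dft import FeatureMatrix

        back = FeatureMatrix.from_hdf5(path)
        np.testing.assert_allclose(back.rows, fm.rows)
        assert list(back.labels) == list(fm.labels)
        assert back.params == fm.params
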