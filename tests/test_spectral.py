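"""Wavelet grid, spectrogram, artifact tagging, baselining and display ops."""

import numpy as np
import pytest

from somnigram import (
    Recording,
    build_frequency_grid,
    compute_baseline_spectrum,
    detect_artifact_windows,
    dominant_frequency,
    mask_line_noise,
    smooth_time,
    subtract_baseline,
    wavelet_spectrogram,
)
from somnigram.errors import (
    ConfigError,
    ContractError,
    InputTooShortError,
    InsufficientDataError,
)
from somnigram.spectral import ArtifactMask, Spectrogram, baseline_valid_steps

FS = 250.0


def tone(freq, minutes, amp=1.0, fs=FS):
    t = np.arange(int(minutes * 60 * fs)) / fs
    return Recording(
        samples=amp * np.sin(2 * np.pi * freq * t)[:, None],
        rate=fs,
        channel_labels=["FF"],
    )


@pytest.fixture(scope="module")
def tone_spec():
    return wavelet_spectrogram(tone(2.0, 10), "FF")


class TestFrequencyGrid:
    def test_window_endpoints(self):
        g = build_frequency_grid()
        w = g.window_s()
        assert w[0] == pytest.approx(3 / 0.1)  # 30 s at 0.1 Hz
        assert w[-1] == pytest.approx(30 / 150)  # 0.2 s at 150 Hz

    def test_two_bins_are_the_endpoints(self):
        g = build_frequency_grid(0.1, 150, 2)
        np.testing.assert_allclose(g.freqs_hz, [0.1, 150])
        np.testing.assert_allclose(g.cycles, [3, 30])

    def test_log_spacing_ratios_constant(self):
        g = build_frequency_grid(0.1, 150, 100)
        ratios = g.freqs_hz[1:] / g.freqs_hz[:-1]
        np.testing.assert_allclose(ratios, 1500 ** (1 / 99), rtol=1e-9)
        assert np.all(np.diff(g.cycles) > 0)

    def test_nonpositive_fmin_rejected(self):
        with pytest.raises(ConfigError):
            build_frequency_grid(0.0, 150, 10)


class TestWaveletSpectrogram:
    def test_pure_tone_peak_within_one_bin(self, tone_spec):
        spec = tone_spec
        unflagged = ~spec.edge_flags.any(axis=1)
        assert unflagged.sum() > 100
        peak_bins = np.argmax(spec.values_db[unflagged], axis=1)
        target = int(np.argmin(np.abs(spec.grid.freqs_hz - 2.0)))
        assert np.abs(peak_bins - target).max() <= 1

    def test_tone_peak_matches_windowed_dft(self, tone_spec):
        """Independent check: the peak frequency of a brute-force DFT over the
        same window agrees with the wavelet's argmax bin."""
        spec = tone_spec
        rec = tone(2.0, 10)
        step = spec.n_steps // 2
        j = int(np.argmax(spec.values_db[step]))
        f_wav = spec.grid.freqs_hz[j]
        # DFT over the wavelet's own window length, centered at the step
        L = int(round(spec.grid.cycles[j] / f_wav * FS))
        c = int(round((step + 0.5) * spec.step_s * FS))
        seg = rec.channel("FF")[c - L // 2 : c - L // 2 + L]
        mags = np.abs(np.fft.rfft(seg * np.hanning(L)))
        f_dft = np.fft.rfftfreq(L, 1 / FS)[np.argmax(mags[1:]) + 1]
        assert abs(f_dft - 2.0) < 0.3
        assert abs(f_wav - 2.0) <= spec.grid.freqs_hz[j + 1] - spec.grid.freqs_hz[j]

    def test_amplitude_doubling_adds_6db(self, tone_spec):
        spec1 = tone_spec
        spec2 = wavelet_spectrogram(tone(2.0, 10, amp=2.0), "FF")
        unflagged = ~spec1.edge_flags.any(axis=1)
        j = int(np.argmax(spec1.values_db[spec1.n_steps // 2]))
        delta = spec2.values_db[unflagged, j] - spec1.values_db[unflagged, j]
        assert np.all(np.abs(delta - 6.02) < 0.05)

    def test_all_zero_signal_hits_floor(self):
        rec = Recording(np.zeros((int(40 * FS), 1)), FS, ["FF"])
        spec = wavelet_spectrogram(rec, "FF")
        assert np.all(spec.values_db == 10 * np.log10(1e-12))

    def test_too_short_recording(self):
        with pytest.raises(InputTooShortError):
            wavelet_spectrogram(tone(2.0, 0.25), "FF")  # 15 s < 30-s window

    def test_step_count(self, tone_spec):
        assert tone_spec.n_steps == int(600 / 0.5)


class TestArtifactDetection:
    def test_spiked_window_flagged_exactly(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(20 * 30 * FS))
        spike = slice(int(5.4 * 30 * FS), int(5.5 * 30 * FS))
        x[spike] += 50.0
        rec = Recording(x[:, None], FS, ["FF"])
        mask = detect_artifact_windows(rec, "FF")
        assert np.flatnonzero(mask.flagged).tolist() == [5]

    def test_leave_one_out_oracle(self):
        """Flags agree with a direct per-window recomputation of the rule."""
        rng = np.random.default_rng(11)
        x = rng.standard_normal(int(12 * 30 * FS)) * (1 + rng.random())
        x[int(2.2 * 30 * FS) : int(2.3 * 30 * FS)] += 30.0
        rec = Recording(x[:, None], FS, ["FF"])
        mask = detect_artifact_windows(rec, "FF")
        wlen = int(30 * FS)
        stats = []
        for w in range(12):
            seg = x[w * wlen : (w + 1) * wlen]
            stats.append(np.abs(seg - seg.mean()).max())
        stats = np.array(stats)
        for w in range(12):
            others = np.delete(stats, w)
            expected = stats[w] > others.mean() + 5 * others.std(ddof=1)
            assert mask.flagged[w] == expected

    def test_identical_windows_none_flagged(self):
        period = np.sin(2 * np.pi * np.arange(int(30 * FS)) / FS)
        rec = Recording(np.tile(period, 5)[:, None], FS, ["FF"])
        mask = detect_artifact_windows(rec, "FF")
        assert mask.flagged.sum() == 0  # equality is not exceedance

    def test_two_windows_insufficient(self):
        rec = Recording(np.random.default_rng(0).normal(size=(int(60 * FS), 1)), FS, ["FF"])
        with pytest.raises(InsufficientDataError):
            detect_artifact_windows(rec, "FF")


def _toy_spec(values, step_s=0.5, f_min=1.0, f_max=64.0):
    n_bins = values.shape[1]
    grid = build_frequency_grid(f_min, f_max, n_bins)
    return Spectrogram(values_db=values, step_s=step_s, grid=grid, stage_tag="raw_db")


class TestBaseline:
    def test_constant_spectrogram(self):
        spec = _toy_spec(np.full((240, 10), 5.0))
        mask = ArtifactMask(30.0, np.zeros(4, bool), np.zeros(4))
        bl = compute_baseline_spectrum(spec, mask)
        np.testing.assert_allclose(bl.mean_db, 5.0)

    def test_flagged_window_excluded(self):
        values = np.zeros((240, 4))
        values[60:120] += 100.0  # window 1 (steps 60..119 at 0.5 s = 30-60 s)
        spec = _toy_spec(values)
        flagged = np.array([False, True, False, False])
        mask = ArtifactMask(30.0, flagged, np.zeros(4))
        bl = compute_baseline_spectrum(spec, mask)
        keep = np.ones(240, bool)
        keep[60:120] = False
        np.testing.assert_allclose(bl.mean_db, values[keep].mean(axis=0))

    def test_all_flagged_falls_back_with_warning(self):
        spec = _toy_spec(np.full((240, 4), 7.0))
        mask = ArtifactMask(30.0, np.ones(4, bool), np.zeros(4))
        with pytest.warns(UserWarning):
            bl = compute_baseline_spectrum(spec, mask)
        np.testing.assert_allclose(bl.mean_db, 7.0)

    def test_subtract_then_mean_is_zero(self):
        rng = np.random.default_rng(5)
        spec = _toy_spec(rng.normal(0, 3, (240, 8)))
        mask = ArtifactMask(30.0, np.array([False, True, False, False]), np.zeros(4))
        bl = compute_baseline_spectrum(spec, mask)
        rel = subtract_baseline(spec, bl)
        valid = baseline_valid_steps(rel, mask)
        for j in range(8):
            assert abs(rel.values_db[valid[:, j], j].mean()) < 1e-9

    def test_subtraction_matches_elementwise_oracle(self):
        rng = np.random.default_rng(6)
        spec = _toy_spec(rng.normal(0, 3, (120, 6)))
        mask = ArtifactMask(30.0, np.zeros(2, bool), np.zeros(2))
        bl = compute_baseline_spectrum(spec, mask)
        rel = subtract_baseline(spec, bl)
        np.testing.assert_array_equal(
            rel.values_db, spec.values_db - bl.mean_db[None, :]
        )
        assert rel.stage_tag == "baselined"


class TestLineMask:
    def _baselined(self, values):
        spec = _toy_spec(values, f_min=1.0, f_max=256.0)
        spec.stage_tag = "baselined"
        return spec

    def test_masked_bins_equal_reference_average(self):
        rng = np.random.default_rng(7)
        values = rng.normal(0, 1, (50, 9))
        spec = self._baselined(values)
        freqs = spec.grid.freqs_hz
        lo, hi = freqs[3] - 1e-9, freqs[5] + 1e-9
        out = mask_line_noise(spec, ((lo, hi),))
        expected = values[:, [1, 2, 6, 7]].mean(axis=1)
        for j in (3, 4, 5):
            np.testing.assert_allclose(out.values_db[:, j], expected)

    def test_known_reference_values(self):
        values = np.zeros((4, 9))
        values[:, 1], values[:, 2] = 1.0, 2.0
        values[:, 6], values[:, 7] = 3.0, 4.0
        spec = self._baselined(values)
        freqs = spec.grid.freqs_hz
        out = mask_line_noise(spec, ((freqs[3] - 1e-9, freqs[5] + 1e-9),))
        assert np.all(out.values_db[:, 3:6] == 2.5)

    def test_empty_band_list_is_identity(self):
        rng = np.random.default_rng(8)
        spec = self._baselined(rng.normal(0, 1, (10, 9)))
        out = mask_line_noise(spec, ())
        np.testing.assert_array_equal(out.values_db, spec.values_db)

    def test_band_at_grid_edge_rejected(self):
        spec = self._baselined(np.zeros((10, 9)))
        with pytest.raises(ConfigError):
            mask_line_noise(spec, ((spec.grid.freqs_hz[0], spec.grid.freqs_hz[2]),))


class TestSmoothing:
    def _baselined(self, values):
        spec = _toy_spec(values)
        spec.stage_tag = "baselined"
        return spec

    def test_constant_unchanged(self):
        spec = self._baselined(np.full((200, 3), 2.5))
        out = smooth_time(spec, 40.0)
        np.testing.assert_allclose(out.values_db, 2.5)
        assert out.stage_tag == "smoothed"

    def test_impulse_spreads_to_1_over_w(self):
        values = np.zeros((400, 2))
        values[200, 0] = 1.0
        out = smooth_time(self._baselined(values), 40.0)  # 80 steps
        interior = out.values_db[165:235, 0]
        np.testing.assert_allclose(interior, 1 / 80)

    def test_matches_windowed_mean_oracle(self):
        rng = np.random.default_rng(9)
        values = rng.normal(0, 1, (137, 2))
        out = smooth_time(self._baselined(values), 10.0)  # 20 steps
        w = 20
        for t in (0, 5, 68, 130, 136):
            lo = max(0, t - w // 2)
            hi = min(137, t + (w + 1) // 2)
            np.testing.assert_allclose(
                out.values_db[t], values[lo:hi].mean(axis=0), atol=1e-12
            )


class TestDominantFrequency:
    def _baselined(self, values):
        spec = _toy_spec(values)
        spec.stage_tag = "baselined"
        return spec

    def test_single_hot_bin(self):
        values = np.full((20, 10), -1.0)
        grid = build_frequency_grid(1.0, 64.0, 10)
        j = int(np.argmin(np.abs(grid.freqs_hz - 2.0)))
        values[:, j] = 5.0
        dots = dominant_frequency(self._baselined(values))
        assert np.all(dots[:, 1] == grid.freqs_hz[j])

    def test_tie_breaks_to_lowest_frequency(self):
        values = np.zeros((5, 10))
        values[:, 2] = 3.0
        values[:, 7] = 3.0
        dots = dominant_frequency(self._baselined(values))
        grid = build_frequency_grid(1.0, 64.0, 10)
        assert np.all(dots[:, 1] == grid.freqs_hz[2])

    def test_matches_argmax_oracle(self):
        rng = np.random.default_rng(10)
        values = rng.normal(0, 1, (60, 12))
        spec = _toy_spec(values)
        spec.stage_tag = "baselined"
        dots = dominant_frequency(spec)
        for t in range(60):
            best = max(range(12), key=lambda j: (values[t, j], -j))
            assert dots[t, 1] == spec.grid.freqs_hz[best]

    def test_rejects_smoothed_input(self):
        spec = _toy_spec(np.zeros((50, 5)))
        spec.stage_tag = "smoothed"
        with pytest.raises(ContractError):
            dominant_frequency(spec)

    def test_rejects_raw_input(self):
        spec = _toy_spec(np.zeros((50, 5)))
        with pytest.raises(ContractError):
            dominant_frequency(spec)
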