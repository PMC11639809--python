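import numpy as np
import pytest

from sheeprr import (
    BandpassConfig,
    RespiratorySignal,
    RRSeries,
    bandpass,
    estimate_rr,
    pca_decompose,
    select_component,
    smooth_rr,
)
from sheeprr.exceptions import DegenerateInputError, ParameterError
from sheeprr.spectral import total_variance
from sheeprr.tracking import MotionSignals


def analytic_bandpass_gain(f, cfg: BandpassConfig, fps: float) -> float:
    """Closed-form magnitude of the digital Butterworth band-pass at f.

    Analog prototype |H(jw)|^2 = 1 / (1 + ((w^2 - w0^2) / (B w))^(2n)),
    evaluated at the bilinear-prewarped frequency g(f) = fs/pi * tan(pi f / fs)
    (the design prewarps the band edges, so the response at any f equals the
    analog response at g(f)).
    """
    warp = lambda x: fps / np.pi * np.tan(np.pi * x / fps)
    wl, wh, w = warp(cfg.low_hz), warp(cfg.high_hz), warp(f)
    w0sq = wl * wh
    b = wh - wl
    return 1.0 / np.sqrt(1.0 + ((w * w - w0sq) / (b * w)) ** (2 * cfg.order))


def sliding_rr_oracle(x, fps, window_s, pad_len, low, high):
    """Brute-force per-window RR: polyfit detrend + explicit DFT over the
    in-band bins + exhaustive argmax."""
    w = int(round(window_s * fps))
    freqs = np.arange(pad_len // 2 + 1) * fps / pad_len
    band = np.flatnonzero((freqs >= low) & (freqs <= high))
    out = []
    j = np.arange(w)
    for start in range(len(x) - w + 1):
        seg = np.asarray(x[start:start + w], dtype=float)
        slope, intercept = np.polyfit(j, seg, 1)
        seg = seg - (slope * j + intercept)
        mags = [abs(np.sum(seg * np.exp(-2j * np.pi * j * k / pad_len))) for k in band]
        out.append(60.0 * freqs[band[int(np.argmax(mags))]])
    return np.array(out)


class TestBandpass:
    def test_dc_rejected(self):
        out = bandpass(np.full(200, 5.0), fps=20.0)
        assert np.max(np.abs(out)) < 1e-3

    def test_inband_tone_preserved(self):
        t = np.arange(1200) / 20.0
        x = np.sin(2 * np.pi * 0.5 * t)
        out = bandpass(x, fps=20.0)
        amp = np.sqrt(2.0) * np.std(out[200:-200])  # transient-free amplitude
        assert 0.9 <= amp <= 1.0 + 1e-3

    @pytest.mark.parametrize("f", [0.15, 1.0, 2.0])
    def test_matches_analytic_gain(self, f):
        cfg = BandpassConfig()
        fps = 20.0
        t = np.arange(8000) / fps
        x = np.sin(2 * np.pi * f * t)
        out = bandpass(x, fps, cfg)
        measured = np.max(np.abs(out[2000:-2000]))
        expected = analytic_bandpass_gain(f, cfg, fps) ** 2  # forward+backward pass
        assert measured == pytest.approx(expected, rel=0.10)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            bandpass(np.zeros(100), fps=1.2)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ParameterError):
            bandpass(np.zeros(5), fps=20.0)


def _motion_from_rows(rows, fps=20.0):
    rows = np.asarray(rows, dtype=float)
    m = len(rows) // 2
    return MotionSignals(dx=rows[:m], dy=rows[m:], fps=fps)


class TestPCA:
    def test_planted_sinusoid_recovered(self, rng):
        t = np.arange(400) / 20.0
        s = np.sin(2 * np.pi * 0.45 * t)
        rows = [s + 0.3 * rng.normal(size=len(t)) for _ in range(10)]
        res = pca_decompose(_motion_from_rows(rows))
        r = np.corrcoef(res.components[0], s)[0, 1]
        assert abs(r) > 0.99

    def test_explained_variance_sums_to_total(self, rng):
        rows = rng.normal(size=(4, 50))
        motion = _motion_from_rows(rows)
        res = pca_decompose(motion, n_components=4)
        assert np.sum(res.explained_variance) == pytest.approx(
            total_variance(motion), abs=1e-9
        )

    def test_two_planted_sources_in_variance_order(self, rng):
        t = np.arange(600) / 20.0
        s1 = 3.0 * np.sin(2 * np.pi * 0.4 * t)
        s2 = 1.0 * np.sin(2 * np.pi * 0.6 * t)  # orthogonal over full periods
        rows = [s1] * 3 + [s2] * 3
        res = pca_decompose(_motion_from_rows(rows), n_components=2)
        assert res.explained_variance[0] > res.explained_variance[1]
        assert abs(np.corrcoef(res.components[0], s1)[0, 1]) > 0.99
        assert abs(np.corrcoef(res.components[1], s2)[0, 1]) > 0.99

    def test_fewer_signals_than_components(self, rng):
        rows = rng.normal(size=(4, 30))
        res = pca_decompose(_motion_from_rows(rows), n_components=6)
        assert res.n_components == 4

    def test_single_signal_rejected(self, rng):
        with pytest.raises(DegenerateInputError):
            pca_decompose(MotionSignals(dx=rng.normal(size=(1, 30)),
                                        dy=np.empty((0, 30)), fps=20.0))


class TestSelectComponent:
    def _pca(self, comps):
        from sheeprr.spectral import PCAResult

        comps = np.asarray(comps, dtype=float)
        var = np.var(comps, axis=1)
        return PCAResult(components=comps, explained_variance=var)

    def test_first_strategy_returns_component_one(self, rng):
        res = self._pca(rng.normal(size=(4, 100)))
        sig = select_component(res, fps=20.0, strategy="first")
        assert sig.component_index == 1

    def test_best_inband_finds_planted_component(self, rng):
        t = np.arange(300) / 20.0
        comps = list(rng.normal(size=(2, 300)) * 5)
        comps.append(np.sin(2 * np.pi * 0.5 * t))  # clean in-band tone at #3
        comps.extend(rng.normal(size=(2, 300)) * 5)
        sig = select_component(self._pca(comps), fps=20.0, strategy="best_inband")
        assert sig.component_index == 3

    def test_single_component_under_both_strategies(self, rng):
        res = self._pca(rng.normal(size=(1, 50)))
        for strategy in ("first", "best_inband"):
            assert select_component(res, 20.0, strategy=strategy).component_index == 1

    def test_selected_signal_is_zero_mean(self, rng):
        res = self._pca(rng.normal(loc=3.0, size=(2, 80)))
        sig = select_component(res, fps=20.0)
        assert abs(sig.samples.mean()) < 1e-9


class TestEstimateRR:
    def test_pure_tone_every_window(self):
        fps = 20.0
        t = np.arange(600) / fps
        sig = RespiratorySignal(np.sin(2 * np.pi * 0.45 * t), fps=fps)
        series = estimate_rr(sig)
        assert len(series) == 600 - 200 + 1
        # every window within two FFT bins; the bulk within one
        assert np.allclose(series.rr_bpm, 27.0, atol=2 * 60.0 * fps / 4096)
        assert abs(np.median(series.rr_bpm) - 27.0) <= 60.0 * fps / 4096

    @pytest.mark.parametrize("fps,expected_window", [(20.0, 200), (10.0, 100)])
    def test_window_length_matches_rate(self, fps, expected_window):
        n = 3 * expected_window
        t = np.arange(n) / fps
        sig = RespiratorySignal(np.sin(2 * np.pi * 0.5 * t), fps=fps)
        series = estimate_rr(sig, window_s=10.0)
        assert len(series) == n - expected_window + 1

    def test_out_of_band_peak_ignored(self):
        fps = 20.0
        t = np.arange(600) / fps
        x = 1.0 * np.sin(2 * np.pi * 0.4 * t) + 3.0 * np.sin(2 * np.pi * 1.5 * t)
        series = estimate_rr(RespiratorySignal(x, fps=fps))
        # the 90 bpm tone never wins despite being 3x stronger; its sidelobe
        # leakage may still nudge single windows by ~1 bpm
        assert abs(np.median(series.rr_bpm) - 24.0) <= 60.0 * fps / 4096
        assert np.allclose(series.rr_bpm, 24.0, atol=1.5)

    def test_emitted_rr_always_inside_band(self, rng):
        fps = 10.0
        x = rng.normal(size=300)  # white noise
        series = estimate_rr(RespiratorySignal(x, fps=fps))
        assert np.all(series.rr_bpm >= 60 * 0.33)
        assert np.all(series.rr_bpm <= 60 * 0.67)
        assert np.all(series.rr_smoothed_bpm >= 60 * 0.33)
        assert np.all(series.rr_smoothed_bpm <= 60 * 0.67)

    def test_window_end_times(self):
        fps = 10.0
        x = np.sin(2 * np.pi * 0.5 * np.arange(150) / fps)
        series = estimate_rr(RespiratorySignal(x, fps=fps))
        assert series.times_s[0] == pytest.approx((100 - 1) / fps)
        assert np.allclose(np.diff(series.times_s), 1.0 / fps)

    def test_matches_bruteforce_oracle(self, rng):
        fps = 10.0
        pad = 256
        for _ in range(10):
            f = rng.uniform(0.3, 0.7)
            t = np.arange(120) / fps
            x = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            x += 0.5 * rng.normal(size=len(t))
            series = estimate_rr(RespiratorySignal(x, fps=fps), window_s=10.0,
                                 pad_len=pad)
            oracle = sliding_rr_oracle(x, fps, 10.0, pad, 0.33, 0.67)
            assert np.allclose(series.rr_bpm, oracle, atol=1e-9)

    def test_short_signal_rejected(self):
        with pytest.raises(DegenerateInputError):
            estimate_rr(RespiratorySignal(np.zeros(50), fps=20.0))


class TestSmoothRR:
    def _series(self, values, fps=20.0):
        values = np.asarray(values, dtype=float)
        times = np.arange(len(values)) / fps
        return RRSeries(times_s=times, rr_bpm=values,
                        rr_smoothed_bpm=values.copy(), fps=fps)

    def test_constant_is_fixed_point(self):
        s = smooth_rr(self._series(np.full(100, 27.0)))
        assert np.allclose(s.rr_smoothed_bpm, 27.0, atol=1e-12)

    def test_alternating_values_average_in_interior(self):
        vals = np.where(np.arange(400) % 2 == 0, 25.0, 29.0)
        s = smooth_rr(self._series(vals), kernel_s=10.0)
        interior = s.rr_smoothed_bpm[150:250]
        assert np.allclose(interior, 27.0, atol=0.05)

    def test_output_within_input_range(self, rng):
        vals = rng.uniform(20, 40, size=200)
        s = smooth_rr(self._series(vals))
        assert s.rr_smoothed_bpm.min() >= vals.min() - 1e-12
        assert s.rr_smoothed_bpm.max() <= vals.max() + 1e-12

    def test_kernel_capped_at_series_length(self):
        vals = np.array([25.0, 27.0, 29.0])
        s = smooth_rr(self._series(vals), kernel_s=100.0)
        assert len(s.rr_smoothed_bpm) == 3

    def test_raw_estimates_untouched(self, rng):
        vals = rng.uniform(20, 40, size=50)
        s = smooth_rr(self._series(vals))
        assert np.array_equal(s.rr_bpm, vals)

    def test_empty_series_rejected(self):
        s = RRSeries(times_s=[], rr_bpm=[], rr_smoothed_bpm=[], fps=20.0)
        with pytest.raises(DegenerateInputError):
            smooth_rr(s)
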