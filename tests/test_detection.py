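import numpy as np
import pytest

import speechdpoae as sd
from speechdpoae._dsp import analytic_signal, delay_samples
from speechdpoae.detection import ComplexCorrelogram


def _noise_template(n=20000, fs=10000.0, seed=0):
    rng = np.random.default_rng(seed)
    return sd.HarmonicWaveform(samples=rng.standard_normal(n), harmonic_n=1, rate_hz=fs)


def _manual_correlogram(values, fs=10000.0, smoothed=None):
    n_lag = (len(values) - 1) // 2
    lags = np.arange(-n_lag, n_lag + 1) / fs
    return ComplexCorrelogram(
        lags_s=lags,
        values=np.asarray(values, dtype=complex),
        normalization_N=1.0,
        rate_hz=fs,
        smoothed_amplitude=smoothed,
        smoothing_len=None if smoothed is None else 1,
    )


class TestComplexXcorr:
    def test_template_autocorrelation_is_one_at_zero_lag(self, male_kit):
        t7 = male_kit["t7"]
        rec = sd.MicRecording(np.array(t7.samples), t7.rate_hz)
        c = sd.complex_xcorr(rec, t7, max_lag_s=0.01)
        zero = np.argmin(np.abs(c.lags_s))
        assert abs(np.abs(c.values[zero]) - 1.0) < 1e-9
        assert abs(np.angle(c.values[zero])) < 1e-6

    def test_hilbert_of_template_reads_quarter_cycle(self, male_kit):
        t7 = male_kit["t7"]
        rec = sd.MicRecording(np.imag(analytic_signal(t7.samples)), t7.rate_hz)
        c = sd.complex_xcorr(rec, t7, max_lag_s=0.01)
        zero = np.argmin(np.abs(c.lags_s))
        assert abs(np.abs(c.values[zero]) - 1.0) < 1e-3
        assert abs(np.angle(c.values[zero]) - np.pi / 2) < 1e-3

    def test_delay_recovery_in_heavy_noise(self):
        fs = 44100.0
        tmpl = _noise_template(n=int(10 * fs), fs=fs, seed=1)
        rng = np.random.default_rng(2)
        delayed = delay_samples(tmpl.samples, int(round(0.002 * fs)))
        noise = 10.0 * np.std(tmpl.samples) * rng.standard_normal(delayed.size)
        rec = sd.MicRecording(delayed + noise, fs)
        c = sd.complex_xcorr(rec, tmpl, max_lag_s=0.01)
        lag_hat = c.lags_s[int(np.argmax(np.abs(c.values)))]
        assert abs(lag_hat - 0.002) <= 1.5 / fs

    def test_zero_template_rejected(self):
        fs = 10000.0
        rec = sd.MicRecording(np.ones(1000), fs)
        tmpl = sd.HarmonicWaveform(np.zeros(1000), 1, fs)
        with pytest.raises(ValueError, match="all-zero template"):
            sd.complex_xcorr(rec, tmpl, max_lag_s=0.01)

    def test_matches_brute_force_lag_loop(self):
        rng = np.random.default_rng(5)
        fs = 1000.0
        r = rng.standard_normal(1000)
        w = rng.standard_normal(1000)
        tmpl = sd.HarmonicWaveform(w, 1, fs)
        rec = sd.MicRecording(r, fs)
        max_lag = 30
        c = sd.complex_xcorr(rec, tmpl, max_lag_s=max_lag / fs)
        a = analytic_signal(w)
        N = 1.0 / (np.linalg.norm(r) * np.linalg.norm(w))
        for i, tau in enumerate(range(-max_lag, max_lag + 1)):
            total = 0.0 + 0.0j
            for t in range(w.size):
                if 0 <= t + tau < r.size:
                    total += r[t + tau] * a[t]
            total *= N
            assert abs(c.values[i] - total) <= 1e-10 * max(abs(total), 1e-30)

    def test_normalization_bound(self, male_kit):
        t7 = male_kit["t7"]
        rng = np.random.default_rng(8)
        rec = sd.MicRecording(
            0.3 * t7.samples + 0.05 * rng.standard_normal(t7.samples.size),
            t7.rate_hz,
        )
        c = sd.complex_xcorr(rec, t7, max_lag_s=0.05)
        assert np.max(np.abs(c.values)) <= 1.0 + 1e-12


class TestEquipmentDelay:
    fs = 44100.0

    def _rec(self, male_kit, d9, d11, noise=1e-4, seed=0):
        rng = np.random.default_rng(seed)
        w9, w11 = male_kit["w9"], male_kit["w11"]
        y = delay_samples(w9.samples, d9) + delay_samples(w11.samples, d11)
        return sd.MicRecording(y + noise * rng.standard_normal(y.size), self.fs)

    def test_zero_delay(self, male_kit):
        rec = self._rec(male_kit, 0, 0)
        d = sd.estimate_equipment_delay(rec, (male_kit["w9"], male_kit["w11"]))
        assert d == pytest.approx(0.0, abs=1.0 / self.fs)

    def test_one_ms_delay(self, male_kit):
        k = int(round(0.001 * self.fs))
        rec = self._rec(male_kit, k, k)
        d = sd.estimate_equipment_delay(rec, (male_kit["w9"], male_kit["w11"]))
        assert d == pytest.approx(0.001, abs=1.0 / self.fs)

    def test_disagreeing_delays_mean_with_warning(self, male_kit):
        k1, k2 = int(round(0.001 * self.fs)), int(round(0.002 * self.fs))
        rec = self._rec(male_kit, k1, k2)
        with pytest.warns(UserWarning, match="disagree"):
            d = sd.estimate_equipment_delay(rec, (male_kit["w9"], male_kit["w11"]))
        assert d == pytest.approx(0.0015, abs=1.0 / self.fs)

    def test_stimuli_absent(self, male_kit):
        rng = np.random.default_rng(3)
        rec = sd.MicRecording(rng.standard_normal(male_kit["w9"].samples.size), self.fs)
        with pytest.raises(ValueError, match="not found"):
            sd.estimate_equipment_delay(rec, (male_kit["w9"], male_kit["w11"]))


class TestPreprocess:
    def test_trim_arithmetic(self):
        rec = sd.MicRecording(np.arange(120000.0), 1000.0)
        out = sd.preprocess(rec, trim_s=3.0, delay_s=0.0)
        assert out.samples.size == 114000

    def test_identity_when_no_trim_no_delay(self):
        rec = sd.MicRecording(np.arange(1000.0), 1000.0)
        out = sd.preprocess(rec, trim_s=0.0, delay_s=0.0)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_delay_compensation_round_trip(self, male_kit):
        fs = 44100.0
        k = int(round(0.001 * fs))
        w9, w11 = male_kit["w9"], male_kit["w11"]
        y = delay_samples(w9.samples, k) + delay_samples(w11.samples, k)
        rec = sd.MicRecording(y, fs)
        d = sd.estimate_equipment_delay(rec, (w9, w11))
        out = sd.preprocess(rec, trim_s=3.0, delay_s=d)
        n_trim = int(round(3.0 * fs))
        w9c = sd.HarmonicWaveform(w9.samples[n_trim:-n_trim], 9, fs)
        w11c = sd.HarmonicWaveform(w11.samples[n_trim:-n_trim], 11, fs)
        d2 = sd.estimate_equipment_delay(out, (w9c, w11c))
        assert abs(d2) <= 1.0 / fs

    def test_too_short(self):
        rec = sd.MicRecording(np.zeros(100), 1000.0)
        with pytest.raises(ValueError, match="shorter"):
            sd.preprocess(rec, trim_s=3.0)


class TestSmoothEnvelope:
    def test_constant_unchanged(self):
        c = _manual_correlogram(np.full(2001, 0.5 + 0.0j))
        out = sd.smooth_envelope(c, 199)
        np.testing.assert_allclose(out.smoothed_amplitude, 0.5, rtol=1e-12)

    def test_impulse_response_is_rectangle(self):
        values = np.zeros(2001, dtype=complex)
        values[1000] = 1.0
        out = sd.smooth_envelope(_manual_correlogram(values), 199)
        box = out.smoothed_amplitude
        assert np.isclose(box[1000], 1.0 / 199)
        assert np.count_nonzero(box > 1e-12) == 199
        np.testing.assert_allclose(box[1000 - 99 : 1000 + 100], 1.0 / 199)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            sd.smooth_envelope(_manual_correlogram(np.ones(101, complex)), 200)

    def test_noise_variance_reduced_by_window_length(self):
        rng = np.random.default_rng(17)
        amp = rng.standard_normal(200001) + 5.0
        c = _manual_correlogram(amp.astype(complex))
        out = sd.smooth_envelope(c, 199)
        inner = slice(1000, -1000)
        ratio = np.var(amp[inner]) / np.var(out.smoothed_amplitude[inner])
        assert 140 < ratio < 280

    def test_complex_values_untouched(self, male_kit):
        t7 = male_kit["t7"]
        rec = sd.MicRecording(np.array(t7.samples), t7.rate_hz)
        c = sd.complex_xcorr(rec, t7, max_lag_s=0.01)
        out = sd.smooth_envelope(c, 199)
        np.testing.assert_array_equal(out.values, c.values)


class TestNoiseFloor:
    fs = 10000.0

    def _lag_count(self):
        return 2 * int(0.75 * self.fs) + 1

    def test_constant_amplitude(self):
        c = _manual_correlogram(np.full(self._lag_count(), 0.2 + 0.0j), self.fs)
        assert sd.noise_floor(c) == pytest.approx(0.2)

    def test_rayleigh_quantile(self):
        rng = np.random.default_rng(23)
        n = self._lag_count()
        sigma = 1.0
        values = sigma * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
        c = _manual_correlogram(values, self.fs)
        analytic_q95 = sigma * np.sqrt(2 * np.log(20.0))
        assert sd.noise_floor(c) == pytest.approx(analytic_q95, rel=0.02)

    def test_peak_inside_70ms_excluded(self):
        values = np.full(self._lag_count(), 0.2 + 0.0j)
        zero = values.size // 2
        values[zero - 100 : zero + 100] = 50.0  # |lag| < 10 ms
        c = _manual_correlogram(values, self.fs)
        assert sd.noise_floor(c) == pytest.approx(0.2)

    def test_insufficient_lag_range(self):
        c = _manual_correlogram(np.ones(101, complex), self.fs)
        with pytest.raises(ValueError, match="noise estimation"):
            sd.noise_floor(c)


class TestFindPeak:
    fs = 10000.0

    def test_requires_smoothing(self):
        c = _manual_correlogram(np.ones(201, complex), self.fs)
        with pytest.raises(ValueError, match="smoothed"):
            sd.find_peak(c, 0.1)

    def test_earliest_lag_wins_ties(self):
        n = 201
        smoothed = np.zeros(n)
        zero = n // 2
        smoothed[zero + 10] = 1.0
        smoothed[zero + 30] = 1.0
        values = np.ones(n, dtype=complex)
        c = _manual_correlogram(values, self.fs, smoothed=smoothed)
        res = sd.find_peak(c, 0.5)
        assert res.latency_s == pytest.approx(10 / self.fs)

    def test_phase_from_unsmoothed_values(self):
        n = 201
        zero = n // 2
        smoothed = np.zeros(n)
        smoothed[zero + 20] = 1.0
        values = np.zeros(n, dtype=complex)
        values[zero + 20] = np.exp(1j * 0.7)
        c = _manual_correlogram(values, self.fs, smoothed=smoothed)
        res = sd.find_peak(c, 0.5)
        assert res.phase_rad == pytest.approx(0.7)
        assert res.significant

    def test_insignificant_result_returned_not_raised(self):
        n = 201
        smoothed = np.full(n, 0.1)
        c = _manual_correlogram(np.full(n, 0.1 + 0j), self.fs, smoothed=smoothed)
        res = sd.find_peak(c, 0.5)
        assert not res.significant
        assert 0.0 <= res.latency_s <= 0.007
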