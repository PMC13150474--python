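import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikesusc import (BaselineStats, CellClass, ResponseStats, Susceptibility2,
                       baseline_stats, classify_cell, firing_rate,
                       project_diagonal, response_modulation, spectrum_peaks,
                       susceptibility_index)
from spikesusc.punit_model import SpikeData


def chi2_from(mag, df=3.90625):
    f = df * np.arange(1, mag.shape[0] + 1)
    return Susceptibility2(f1_hz=f, f2_hz=f, values=mag.astype(complex),
                           n_segments=1)


class TestBaselineStats:
    def test_periodic_train(self, periodic_spikes):
        b = baseline_stats(periodic_spikes)
        assert b.rate_hz == pytest.approx(100.0)
        assert b.cv == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(b.serial_corr_lag1)  # constant ISI series: flagged

    def test_poisson_cv_is_one(self, poisson_spikes):
        b = baseline_stats(poisson_spikes)
        assert b.cv == pytest.approx(1.0, abs=0.02)

    def test_perfect_locking_gives_unit_vector_strength(self):
        f_eod = 800.0
        t = np.arange(1, 400) / f_eod  # one spike per EOD cycle peak
        b = baseline_stats(SpikeData(trials=[t], duration_s=0.5),
                           f_eod=f_eod)
        assert b.vector_strength == pytest.approx(1.0, abs=1e-9)

    def test_vector_strength_from_eod_trace_zero_crossings(self):
        from spikesusc import eod_carrier
        f_eod = 750.0
        tr = eod_carrier(f_eod, 1.0, dt=5e-5)
        t = np.arange(1, 700) / f_eod
        b = baseline_stats(SpikeData(trials=[t], duration_s=1.0),
                           eod_trace=tr)
        assert b.vector_strength > 0.99

    def test_single_spike_has_undefined_cv(self):
        b = baseline_stats(SpikeData(trials=[np.array([0.5])],
                                     duration_s=1.0))
        assert np.isnan(b.cv)
        assert b.rate_hz == pytest.approx(1.0)

    def test_negative_serial_correlation_of_alternating_isis(self):
        isis = np.tile([0.01, 0.02], 200)
        t = np.cumsum(isis)
        b = baseline_stats(SpikeData(trials=[t], duration_s=t[-1] + 0.01))
        assert b.serial_corr_lag1 == pytest.approx(-1.0, abs=0.01)


class TestFiringRate:
    def test_single_spike_kernel_has_unit_area(self):
        spikes = SpikeData(trials=[np.array([0.5])], duration_s=1.0)
        t, r = firing_rate(spikes, dt=1e-4)
        assert np.trapezoid(r, t) == pytest.approx(1.0, rel=1e-3)

    def test_time_mean_matches_rate(self, poisson_spikes):
        t, r = firing_rate(poisson_spikes)
        assert r.mean() == pytest.approx(poisson_spikes.rate_hz(), rel=0.01)

    def test_one_ms_kernel_barely_attenuates_100_hz(self):
        # 100 Hz rate modulation passes the 1 ms Gaussian kernel with less
        # than 3% amplitude loss: transfer exp(-(2 pi f sigma)^2 / 2)
        rng = np.random.default_rng(7)
        dur, r0, a, fmod = 40.0, 400.0, 100.0, 100.0
        tt = rng.uniform(0, dur, rng.poisson(2 * r0 * dur))
        keep = rng.uniform(0, 1, len(tt)) < \
            (r0 + a * np.sin(2 * np.pi * fmod * tt)) / (2 * r0)
        ts = np.sort(tt[keep])
        spikes = SpikeData(trials=[ts], duration_s=dur)
        t, r = firing_rate(spikes, dt=2.5e-4)
        quad = 2 * np.abs(np.exp(-2j * np.pi * fmod * t) @ r) / len(r)
        # reference: the same quadrature on the raw point process, so that
        # the shared shot noise cancels and only the kernel transfer remains
        raw = 2 * np.abs(np.exp(-2j * np.pi * fmod * ts).sum()) / dur
        transfer = np.exp(-0.5 * (2 * np.pi * fmod * 1e-3) ** 2)
        assert quad / raw == pytest.approx(transfer, rel=0.01)
        assert transfer > 0.8  # 1 ms kernel keeps 100 Hz modulations


class TestResponseModulation:
    def test_constant_rate_has_zero_modulation(self):
        assert response_modulation(np.full(1000, 80.0)
                                   ).response_modulation_hz == 0.0

    def test_sinusoidal_modulation_std(self):
        t = np.arange(0, 1.0, 1e-4)
        r = 100.0 + 20.0 * np.sin(2 * np.pi * 50.0 * t)
        stats = response_modulation(r)
        assert stats.response_modulation_hz == pytest.approx(20 / np.sqrt(2),
                                                             rel=0.01)
        assert stats.mean_rate_hz == pytest.approx(100.0, rel=0.01)


class TestProjectDiagonal:
    def test_constant_matrix_projects_to_constant(self):
        proj = project_diagonal(chi2_from(np.full((8, 8), 3.0)))
        assert np.allclose(proj.values, 3.0)
        assert len(proj.values) == 15

    def test_single_cell_spreads_over_its_anti_diagonal(self):
        mag = np.zeros((10, 10))
        mag[2, 5] = 7.0
        mag[5, 2] = 7.0
        proj = project_diagonal(chi2_from(mag))
        k = 7  # anti-diagonal index of (2, 5)
        assert proj.values[k] == pytest.approx(2 * 7.0 / proj.counts[k])
        assert proj.counts[k] == 8

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=2, max_value=12),
           st.integers(min_value=0, max_value=1000))
    def test_matches_brute_force_and_conserves_mass(self, m, seed):
        rng = np.random.default_rng(seed)
        mag = np.abs(rng.standard_normal((m, m)))
        mag = 0.5 * (mag + mag.T)
        proj = project_diagonal(chi2_from(mag))
        brute = [np.mean([mag[i, j] for i in range(m) for j in range(m)
                          if i + j == k]) for k in range(2 * m - 1)]
        assert np.allclose(proj.values, brute)
        assert np.sum(proj.values * proj.counts) == pytest.approx(mag.sum())

    def test_sum_frequency_axis(self):
        proj = project_diagonal(chi2_from(np.ones((4, 4)), df=4.0))
        assert np.allclose(proj.sum_freqs_hz, [8, 12, 16, 20, 24, 28, 32])


def flat_projection(r_hz=100.0, df=2.0, level=1.0):
    mag_len = int(2 * r_hz / df)
    mag = np.full((mag_len, mag_len), level)
    return project_diagonal(chi2_from(mag, df=df))


class TestSusceptibilityIndex:
    def test_flat_projection_gives_exactly_one(self):
        si = susceptibility_index(flat_projection(), 100.0)
        assert si.si == 1.0

    def test_single_elevated_bin_gives_its_ratio(self):
        proj = flat_projection(df=2.0)
        k = np.argmin(np.abs(proj.sum_freqs_hz - 100.0))
        proj.values[k] *= 3.0
        si = susceptibility_index(proj, 100.0)
        assert si.si == pytest.approx(3.0)
        assert si.f_peak_hz == proj.sum_freqs_hz[k]

    def test_scale_invariance(self):
        proj = flat_projection(df=2.0)
        k = np.argmin(np.abs(proj.sum_freqs_hz - 90.0))
        proj.values[k] *= 2.5
        a = susceptibility_index(proj, 100.0).si
        proj.values *= 17.3
        b = susceptibility_index(proj, 100.0).si
        assert a == pytest.approx(b, rel=1e-12)

    def test_peak_must_lie_within_50_hz_of_rate(self):
        proj = flat_projection(df=2.0)
        k = np.argmin(np.abs(proj.sum_freqs_hz - 160.0))
        proj.values[k] *= 10.0  # outside [r-50, r+50]: must be ignored
        si = susceptibility_index(proj, 100.0)
        assert si.si == 1.0
        assert abs(si.f_peak_hz - 100.0) <= 50.0

    def test_missing_reference_band_raises(self):
        proj = flat_projection(r_hz=30.0, df=2.0)
        proj.values[0] *= 10.0  # peak at the lowest sum frequency (4 Hz)
        with pytest.raises(ValueError, match="reference band"):
            # left reference window [-16, -6] Hz does not exist
            susceptibility_index(proj, 20.0)

    def test_argmax_ties_break_toward_rate(self):
        proj = flat_projection(df=2.0)
        si = susceptibility_index(proj, 101.0)
        assert abs(si.f_peak_hz - 101.0) <= 1.0


class TestSpectrumPeaks:
    def test_pure_tone_amplitude(self):
        dt, dur, a, f0 = 5e-4, 2.0, 12.0, 40.0
        t = np.arange(0, dur, dt)
        x = 80.0 + a * np.cos(2 * np.pi * f0 * t)
        n = len(x)
        psd = (dt / n) * np.abs(np.fft.rfft(x - x.mean())) ** 2
        freqs = np.fft.rfftfreq(n, dt)
        amp = spectrum_peaks(freqs, psd, [f0])[0]
        assert amp == pytest.approx(a, rel=0.02)

    def test_target_beyond_nyquist_rejected(self):
        freqs = np.linspace(0, 500, 100)
        with pytest.raises(ValueError, match="Nyquist"):
            spectrum_peaks(freqs, np.ones(100), [600.0])

    def test_floor_is_subtracted(self):
        freqs = np.arange(0, 500, 0.5)
        psd = np.full(len(freqs), 4.0)
        amp = spectrum_peaks(freqs, psd, [100.0])[0]
        assert amp == 0.0


class TestClassifyCell:
    @staticmethod
    def stats(rate, cv, vs, sc):
        return BaselineStats(rate_hz=rate, cv=cv, vector_strength=vs,
                             serial_corr_lag1=sc, duration_s=30.0)

    def test_typical_punit(self):
        b = self.stats(200.0, 0.5, 0.8, -0.3)
        resp = ResponseStats(mean_rate_hz=200.0, response_modulation_hz=120.0)
        assert classify_cell(b, resp, cv_stim=1.0) is CellClass.PUNIT

    def test_typical_ampullary(self):
        b = self.stats(130.0, 0.09, 0.05, -0.05)
        resp = ResponseStats(mean_rate_hz=130.0, response_modulation_hz=40.0)
        assert classify_cell(b, resp, cv_stim=0.5) is CellClass.AMPULLARY

    def test_intermediate_locking_is_unclassified(self):
        b = self.stats(100.0, 0.3, 0.5, -0.2)
        resp = ResponseStats(mean_rate_hz=100.0, response_modulation_hz=50.0)
        assert classify_cell(b, resp, cv_stim=0.5) is CellClass.UNCLASSIFIED

    @pytest.mark.parametrize("field,value", [
        ("vs", 0.96), ("rate", 25.0), ("sc", 0.1), ("cv", 1.6)])
    def test_each_punit_threshold_is_binding(self, field, value):
        kw = dict(rate=200.0, cv=0.5, vs=0.8, sc=-0.3)
        kw[field] = value
        b = self.stats(**kw)
        resp = ResponseStats(mean_rate_hz=200.0, response_modulation_hz=120.0)
        assert classify_cell(b, resp, cv_stim=1.0) is not CellClass.PUNIT

    def test_ampullary_response_modulation_bound(self):
        b = self.stats(130.0, 0.09, 0.05, -0.05)
        resp = ResponseStats(mean_rate_hz=130.0, response_modulation_hz=90.0)
        assert classify_cell(b, resp, cv_stim=0.5) is CellClass.UNCLASSIFIED

    def test_thresholds_are_table_driven(self):
        b = self.stats(130.0, 0.09, 0.05, -0.05)
        resp = ResponseStats(mean_rate_hz=130.0, response_modulation_hz=40.0)
        strict = dict(vs_max=0.15, rate_min_hz=10.0, cv_base_max=0.05,
                      cv_stim_max=1.0, sigma_s_max_hz=80.0)
        assert classify_cell(b, resp, 0.5, ampullary_thresholds=strict) \
            is CellClass.UNCLASSIFIED
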