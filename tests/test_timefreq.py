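"""Morlet family contract, transform properties, power and PLF maps."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from aepkit import (EffectParams, EpochedTrials, SubjectRecord, TFCoefficients,
                    epoch_and_centre, evoked_power, make_paired_pulse_schedule,
                    make_wavelet_family, phase_locking_factor,
                    synthesize_session, total_power, wavelet_transform)


def _trials(data, fs=1000.0, kinds=None):
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, None, :]
    t = np.arange(data.shape[2]) / fs
    kinds = kinds or ["S1"] * data.shape[0]
    return EpochedTrials(data, t, fs, np.array(kinds))


def fitted_spectral_sd(kernel, fs, nfft=1 << 15):
    """Gaussian fit to the kernel's magnitude spectrum -> (mu, sigma)."""
    spec = np.abs(np.fft.fft(kernel, nfft)) / fs
    freqs = np.fft.fftfreq(nfft, 1.0 / fs)

    def gauss(f, a, mu, s):
        return a * np.exp(-0.5 * ((f - mu) / s) ** 2)

    p0 = [spec.max(), freqs[np.argmax(spec)], freqs[np.argmax(spec)] / 2 + 0.1]
    popt, _ = curve_fit(gauss, freqs, spec, p0=p0, maxfev=10_000)
    return popt[1], abs(popt[2])


class TestWaveletFamily:
    def test_sigma_relations(self):
        fam = make_wavelet_family()
        assert np.allclose(fam.sigma_f, fam.f0)
        assert np.allclose(fam.sigma_t, 1.0 / (2 * np.pi * fam.sigma_f))
        # log spacing: constant neighbour ratio
        ratios = fam.f0[1:] / fam.f0[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_two_step_family_is_endpoints(self):
        fam = make_wavelet_family(0.5, 100.0, n_steps=2)
        assert np.allclose(fam.f0, [0.5, 100.0])

    def test_unit_energy(self):
        fam = make_wavelet_family()
        for kernel in fam.kernels:
            energy = np.sum(np.abs(kernel) ** 2) / fam.fs
            assert energy == pytest.approx(1.0, abs=1e-3)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            make_wavelet_family(0.5, 600.0, fs=1000.0)

    def test_spectral_sd_equals_f0(self):
        fam = make_wavelet_family(n_steps=9)
        for i in range(fam.n_freqs):
            _, sigma = fitted_spectral_sd(fam.kernels[i], fam.fs)
            assert fam.f0[i] / sigma == pytest.approx(1.0, rel=0.02)


class TestTransform:
    def test_zero_signal_gives_zero_coefficients(self):
        fam = make_wavelet_family(2, 80, 5, fs=500.0)
        coeffs = wavelet_transform(_trials(np.zeros((3, 200)), 500.0), fam)
        assert np.all(coeffs.values == 0)

    def test_linearity(self):
        fam = make_wavelet_family(2, 80, 5, fs=500.0)
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal((2, 2, 300))
        ca = wavelet_transform(_trials(a, 500.0), fam).values
        cb = wavelet_transform(_trials(b, 500.0), fam).values
        cab = wavelet_transform(_trials(a + b, 500.0), fam).values
        assert np.allclose(cab, ca + cb, rtol=1e-9, atol=1e-12)

    def test_pure_cosine_matches_gaussian_spectral_response(self):
        # closed form: a unit cosine at f contributes both spectral lines
        # +-f, each weighted by the kernel's Gaussian spectrum
        # W(g) = A sqrt(2 pi) sigma_t exp(-(g-f0)^2 / (2 sigma_f^2)), so the
        # RMS coefficient magnitude is sqrt(a^2 + b^2) with a = W(f)/2,
        # b = W(-f)/2 (the -f term matters for this broadband family).
        fs = 1000.0
        fam = make_wavelet_family(5, 100, 13, fs=fs)
        t = np.arange(2000) / fs
        coeffs = wavelet_transform(_trials(np.cos(2 * np.pi * 40 * t)[None], fs),
                                   fam)
        mag = np.abs(coeffs.values[0])
        mid = ~coeffs.coi  # away from epoch edges
        rms = np.array([np.sqrt(np.mean(mag[i, mid[i]] ** 2))
                        for i in range(fam.n_freqs)])
        prefactor = fam.amplitude * np.sqrt(2 * np.pi) * fam.sigma_t
        a = 0.5 * prefactor * np.exp(-((40.0 - fam.f0) ** 2) / (2 * fam.sigma_f**2))
        b = 0.5 * prefactor * np.exp(-((40.0 + fam.f0) ** 2) / (2 * fam.sigma_f**2))
        expected = np.sqrt(a**2 + b**2)
        assert np.allclose(rms, expected, rtol=0.02, atol=1e-3 * expected.max())
        # for this single-cycle family (sigma_f = f0) the response peak sits
        # below the stimulus frequency, at the argmax of the closed form
        assert np.argmax(rms) == np.argmax(expected)
        # near 15 Hz the -40 Hz leakage is negligible, so the magnitude is
        # time-uniform away from edges
        i = fam.nearest(15.0)
        row = mag[i, mid[i]]
        assert row.std() / row.mean() < 0.01

    def test_sampling_rate_mismatch_rejected(self):
        fam = make_wavelet_family(2, 80, 5, fs=500.0)
        with pytest.raises(ValueError):
            wavelet_transform(_trials(np.zeros((1, 100)), 1000.0), fam)


class TestPowerMaps:
    def test_single_trial_total_power(self):
        fam = make_wavelet_family(2, 80, 5, fs=500.0)
        trials = _trials(np.random.default_rng(0).standard_normal((1, 300)),
                         500.0)
        coeffs = wavelet_transform(trials, fam)
        tot = total_power(coeffs)
        assert np.allclose(tot.values, np.abs(coeffs.values[0]) ** 2)

    def test_baseline_self_normalisation(self):
        fam = make_wavelet_family(5, 60, 7, fs=500.0)
        rng = np.random.default_rng(1)
        trials = _trials(rng.standard_normal((60, 500)), 500.0)
        coeffs = wavelet_transform(trials, fam)
        tot = total_power(coeffs, baseline_window=(0.1, 0.4))
        mid = (tot.time_axis > 0.15) & (tot.time_axis < 0.85)
        vals = tot.values[:, mid]
        # stationary noise: ratio map ~ 1 (loose: trial-to-trial SE)
        assert np.abs(np.median(vals) - 1.0) < 0.2

    def test_zero_length_baseline_rejected(self):
        fam = make_wavelet_family(5, 60, 3, fs=500.0)
        coeffs = wavelet_transform(
            _trials(np.ones((2, 200)), 500.0), fam)
        with pytest.raises(ValueError):
            total_power(coeffs, baseline_window=(0.1, 0.1))

    def test_identical_trials_evoked_equals_total(self):
        fam = make_wavelet_family(5, 60, 5, fs=500.0)
        x = np.random.default_rng(2).standard_normal(300)
        trials = _trials(np.tile(x, (8, 1)), 500.0)
        ev = evoked_power(trials, fam)
        tot = total_power(wavelet_transform(trials, fam))
        assert np.allclose(ev.values, tot.values, rtol=1e-10)

    def test_evoked_never_exceeds_total(self):
        fam = make_wavelet_family(5, 60, 6, fs=500.0)
        rng = np.random.default_rng(3)
        trials = _trials(rng.standard_normal((20, 250)), 500.0)
        ev = evoked_power(trials, fam)
        tot = total_power(wavelet_transform(trials, fam))
        assert np.all(ev.values <= tot.values * (1 + 1e-9))

    def test_random_phase_evoked_vanishes(self):
        # N sinusoid trials with uniform random phase: evoked/total ~ 1/N
        fs, n, n_trials = 500.0, 400, 1000
        rng = np.random.default_rng(4)
        t = np.arange(n) / fs
        phases = rng.uniform(0, 2 * np.pi, n_trials)
        data = np.cos(2 * np.pi * 40 * t[None, :] + phases[:, None])
        fam = make_wavelet_family(20, 80, 5, fs=fs)
        trials = _trials(data, fs)
        ev = evoked_power(trials, fam)
        tot = total_power(wavelet_transform(trials, fam))
        i, j = fam.nearest(40.0), n // 2
        assert ev.values[i, j] / tot.values[i, j] < 0.01

    def test_injected_induced_gain_recovered(self, short_schedule):
        # doubling induced_gain quadruples burst amplitude power contribution;
        # compare at the burst pixel with phase-random (kappa=0) bursts
        fs = 500.0
        maps = {}
        for gain in (1.0, 2.0):
            params = EffectParams(p1_scale=0, n1_scale=0, evoked_gain=0,
                                  induced_gain=gain, noise_sd=0.5,
                                  plf_kappa=0.0, late_delta_drop=0.0)
            sched = make_paired_pulse_schedule(n_trials=100, s1_s2_gap=0.5,
                                               inter_trial_gap=0.5)
            rec = synthesize_session(
                sched, SubjectRecord("s", "control", "saline", params), fs,
                seed=9)
            epochs = epoch_and_centre(rec, sched, (-0.1, 0.2), (0.0,),
                                      centering="none")
            fam = make_wavelet_family(15, 60, 7, fs=fs)
            coeffs = wavelet_transform(epochs, fam)
            maps[gain] = total_power(coeffs).pixel(30.0, 0.04)
        assert maps[2.0] / maps[1.0] == pytest.approx(4.0, rel=0.25)


class TestPhaseLockingFactor:
    def _coeffs(self, values, fs=500.0):
        values = np.asarray(values, dtype=complex)
        nf, nt = values.shape[1:]
        return TFCoefficients(values, np.arange(nf) + 1.0,
                              np.arange(nt) / fs, fs,
                              np.zeros((nf, nt), dtype=bool))

    def test_identical_trials_give_one(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((1, 4, 50)) + 1j * rng.standard_normal((1, 4, 50))
        plf = phase_locking_factor(self._coeffs(np.repeat(base, 20, axis=0)))
        assert np.allclose(plf.values, 1.0)

    def test_antipodal_phases_cancel(self):
        values = np.stack([np.ones((2, 5)), -np.ones((2, 5))]).astype(complex)
        plf = phase_locking_factor(self._coeffs(values))
        assert np.allclose(plf.values, 0.0, atol=1e-12)

    def test_random_phase_rayleigh_bound(self):
        rng = np.random.default_rng(5)
        phases = rng.uniform(0, 2 * np.pi, (400, 20, 100))
        plf = phase_locking_factor(self._coeffs(np.exp(1j * phases)))
        assert (plf.values < 3 / np.sqrt(400)).mean() >= 0.99

    def test_invariant_to_positive_trial_rescaling(self):
        rng = np.random.default_rng(6)
        values = rng.standard_normal((10, 3, 40)) + 1j * rng.standard_normal((10, 3, 40))
        scales = rng.uniform(0.1, 9.0, 10)[:, None, None]
        a = phase_locking_factor(self._coeffs(values)).values
        b = phase_locking_factor(self._coeffs(values * scales)).values
        assert np.allclose(a, b)

    def test_all_zero_pixels_are_missing(self):
        values = np.ones((4, 2, 10), dtype=complex)
        values[:, 0, 0] = 0.0
        plf = phase_locking_factor(self._coeffs(values))
        assert np.isnan(plf.values[0, 0])
        assert plf.n_undefined == 1
        assert np.allclose(plf.values[1], 1.0)

    def test_plf_increases_with_kappa(self, short_schedule):
        fs = 500.0
        sched = make_paired_pulse_schedule(n_trials=200, s1_s2_gap=0.5,
                                           inter_trial_gap=0.5)
        fam = make_wavelet_family(15, 60, 7, fs=fs)
        plf_at_burst = {}
        for kappa in (0.0, 1.0, 10.0):
            params = EffectParams(noise_sd=5.0, plf_kappa=kappa,
                                  induced_gain=0.0)
            rec = synthesize_session(
                sched, SubjectRecord("s", "control", "saline", params), fs,
                seed=21)
            epochs = epoch_and_centre(rec, sched, (-0.1, 0.2), (0.0,),
                                      kind="S1")
            coeffs = wavelet_transform(epochs, fam)
            plf_at_burst[kappa] = phase_locking_factor(coeffs).pixel(30.0, 0.04)
        assert plf_at_burst[0.0] < plf_at_burst[1.0] < plf_at_burst[10.0]
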