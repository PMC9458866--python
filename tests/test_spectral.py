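"""Whole-record decomposition, coherence, and oscillation extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import trapezoid

import megtomo as mt
from megtomo.exceptions import NonFiniteDataError, NyquistError, ZeroAmplitudeError

from .conftest import tone_recording


def random_row(rng, k):
    """Random (a, b) coefficient row packaged as a 1-frequency decomposition."""
    a = rng.normal(size=k)
    b = rng.normal(size=k)
    return mt.SpectralDecomposition(
        frequencies=np.array([2.0]),
        cos_coeffs=a[None, :],
        sin_coeffs=b[None, :],
        duration=10.0,
    )


class TestComputeSpectrum:
    def test_single_grid_tone_recovers_amplitude(self):
        rec = tone_recording([[3.0]], [10.0], [0.0], fs=200.0, duration=10.0)
        d = mt.compute_spectrum(rec, 50.0)
        n = d.freq_index(10.0)
        assert d.amplitudes[n - 1, 0] == pytest.approx(3.0, abs=1e-9)
        rest = np.delete(d.amplitudes[:, 0], n - 1)
        assert rest.max() < 1e-9

    def test_all_zero_recording_gives_zero_coefficients(self):
        rec = mt.MultichannelRecording(np.zeros((3, 400)), 100.0)
        d = mt.compute_spectrum(rec, 40.0)
        assert not d.cos_coeffs.any() and not d.sin_coeffs.any()

    def test_matches_quadrature_oracle(self):
        """FFT coefficients vs direct trapezoid quadrature of the integrals."""
        fs, T = 200.0, 5.0
        amps = np.array([[2.0, 0.7], [0.5, 1.5]])   # 2 channels x 2 tones
        freqs = np.array([3.0, 11.2])
        phases = np.array([0.3, 1.1])
        rec = tone_recording(amps, freqs, phases, fs=fs, duration=T)
        d = mt.compute_spectrum(rec, 50.0)
        # oracle: dense trapezoid over [0, T] of the analytic signal
        tq = np.linspace(0.0, T, 20001)
        sig = amps @ np.sin(2 * np.pi * np.outer(freqs, tq) + phases[:, None])
        max_rho = d.amplitudes.max()
        for n in (d.freq_index(3.0), d.freq_index(11.2)):
            nu = d.frequencies[n - 1]
            a_or = (2 / T) * trapezoid(sig * np.cos(2 * np.pi * nu * tq), tq, axis=1)
            b_or = (2 / T) * trapezoid(sig * np.sin(2 * np.pi * nu * tq), tq, axis=1)
            assert np.abs(d.cos_coeffs[n - 1] - a_or).max() < 1e-6 * max_rho
            assert np.abs(d.sin_coeffs[n - 1] - b_or).max() < 1e-6 * max_rho

    def test_rejects_numax_above_nyquist(self):
        rec = mt.MultichannelRecording(np.zeros((1, 100)), 100.0)
        with pytest.raises(NyquistError):
            mt.compute_spectrum(rec, 60.0)

    def test_rejects_non_finite_samples(self):
        data = np.zeros((1, 100))
        data[0, 3] = np.nan
        rec = mt.MultichannelRecording(data, 100.0)
        with pytest.raises(NonFiniteDataError):
            mt.compute_spectrum(rec, 40.0)

    def test_frequency_grid_step_is_inverse_duration(self):
        rec = mt.MultichannelRecording(np.zeros((1, 3000)), 10.0)
        d = mt.compute_spectrum(rec, 5.0)
        steps = np.diff(d.frequencies)
        assert np.allclose(steps, 1.0 / 300.0, rtol=0, atol=1e-15)


class TestRestore:
    def test_single_tone_round_trip(self):
        rec = tone_recording([[3.0]], [10.0], [0.7], fs=200.0, duration=10.0)
        d = mt.compute_spectrum(rec, 50.0)
        restored = mt.restore_frequency_signal(d, d.freq_index(10.0), rec.times)
        err = np.abs(restored - rec.samples).max() / np.abs(rec.samples).max()
        assert err < 1e-6

    def test_phase_half_pi_at_time_zero_gives_amplitude(self):
        d = mt.SpectralDecomposition(
            frequencies=np.array([1.0]),
            cos_coeffs=np.array([[2.5]]),   # a=rho, b=0 -> phi=pi/2
            sin_coeffs=np.array([[0.0]]),
            duration=10.0,
        )
        val = mt.restore_frequency_signal(d, 1, np.array([0.0]))
        assert val[0, 0] == pytest.approx(2.5)

    def test_sum_over_frequencies_is_band_limited_signal(self, rng):
        """Inverse-DFT completeness: all rows together restore the input."""
        fs, T = 100.0, 4.0
        data = rng.normal(size=(3, int(fs * T)))
        rec = mt.MultichannelRecording(data, fs)
        d = mt.compute_spectrum(rec, 50.0)
        total = np.zeros_like(data)
        for n in range(1, d.n_frequencies + 1):
            total += mt.restore_frequency_signal(d, n, rec.times)
        # band-limited reference: drop DC and the (excluded) Nyquist bin
        spec = np.fft.rfft(data, axis=1)
        spec[:, 0] = 0.0
        spec[:, d.n_frequencies + 1 :] = 0.0
        ref = np.fft.irfft(spec, n=data.shape[1], axis=1)
        assert np.abs(total - ref).max() < 1e-6 * np.abs(ref).max()

    def test_index_out_of_range(self, rng):
        d = random_row(rng, 4)
        with pytest.raises(IndexError):
            mt.restore_frequency_signal(d, 2, np.zeros(3))


class TestCoherence:
    def test_equal_phases_give_one(self, rng):
        rho = rng.uniform(0.5, 2.0, size=8)
        phi = 0.9
        d = mt.SpectralDecomposition(
            frequencies=np.array([1.0]),
            cos_coeffs=(rho * np.sin(phi))[None, :],
            sin_coeffs=(rho * np.cos(phi))[None, :],
            duration=10.0,
        )
        assert mt.coherence(d, 1) == pytest.approx(1.0, abs=1e-12)

    def test_quadrature_pair_gives_zero(self):
        d = mt.SpectralDecomposition(
            frequencies=np.array([1.0]),
            cos_coeffs=np.array([[1.0, 0.0]]),   # phases pi/2 and 0
            sin_coeffs=np.array([[0.0, 1.0]]),
            duration=10.0,
        )
        assert mt.coherence(d, 1) == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_row_is_signaled(self):
        d = mt.SpectralDecomposition(
            frequencies=np.array([1.0]),
            cos_coeffs=np.zeros((1, 3)),
            sin_coeffs=np.zeros((1, 3)),
            duration=10.0,
        )
        with pytest.raises(ZeroAmplitudeError):
            mt.coherence(d, 1)

    def test_closed_form_matches_time_sampling_oracle(self):
        """min/max of the instantaneous power over a densely sampled period."""
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(1000):
            k = rng.integers(1, 17)
            rho = rng.uniform(0.0, 2.0, size=k)
            phi = rng.uniform(-np.pi, np.pi, size=k)
            if not np.any(rho > 0):
                continue
            d = mt.SpectralDecomposition(
                frequencies=np.array([2.0]),
                cos_coeffs=(rho * np.sin(phi))[None, :],
                sin_coeffs=(rho * np.cos(phi))[None, :],
                duration=10.0,
            )
            t = np.linspace(0.0, 0.5, 10_000, endpoint=False)
            power = np.sum(
                (rho[:, None] * np.sin(2 * np.pi * 2.0 * t + phi[:, None])) ** 2,
                axis=0,
            )
            oracle = 1.0 - power.min() / power.max()
            worst = max(worst, abs(mt.coherence(d, 1) - oracle))
        assert worst < 1e-6


class TestExtractOscillations:
    def test_coherent_row_yields_one_oscillation(self, rng):
        rho = rng.uniform(0.5, 2.0, size=6)
        d = mt.SpectralDecomposition(
            frequencies=np.array([2.0]),
            cos_coeffs=np.zeros((1, 6)),
            sin_coeffs=rho[None, :],
            duration=10.0,
        )
        oscs = mt.extract_oscillations(d, 1)
        assert len(oscs) == 1
        assert oscs[0].amplitude == pytest.approx(np.sqrt(np.sum(rho**2)))
        assert np.linalg.norm(oscs[0].pattern) == pytest.approx(1.0)

    def test_all_zero_row_yields_empty_list(self):
        d = mt.SpectralDecomposition(
            frequencies=np.array([2.0]),
            cos_coeffs=np.zeros((1, 6)),
            sin_coeffs=np.zeros((1, 6)),
            duration=10.0,
        )
        assert mt.extract_oscillations(d, 1) == []

    def test_pattern_sign_convention_reconstructs_signal(self, rng):
        """D * pattern * sin(wt + phase) must equal the row's signal when
        channel phases are 0 or pi (signed lobes of one dipolar source)."""
        rho = rng.uniform(0.5, 2.0, size=8)
        signs = rng.choice([-1.0, 1.0], size=8)
        phi0 = 0.4
        a = rho * signs * np.sin(phi0)
        b = rho * signs * np.cos(phi0)
        d = mt.SpectralDecomposition(
            frequencies=np.array([2.0]),
            cos_coeffs=a[None, :],
            sin_coeffs=b[None, :],
            duration=10.0,
        )
        assert mt.coherence(d, 1) == pytest.approx(1.0, abs=1e-12)
        (osc,) = mt.extract_oscillations(d, 1)
        t = np.linspace(0.0, 1.0, 64)
        ref = mt.restore_frequency_signal(d, 1, t)
        assert np.abs(osc.signal(t) - ref).max() < 1e-9 * np.abs(ref).max()

    def test_two_phase_shifted_dipoles_are_separated(self, mini_phantom):
        """Two same-frequency dipoles in exact quadrature: the split must
        recover both forward patterns (up to sign/order)."""
        sensors = mini_phantom["sensors"]
        center = mini_phantom["spec"].head_center
        d1 = mt.CurrentDipole(center + [0.03, 0.0, 0.04], [0.0, 1e-8, 0.0])
        d2 = mt.CurrentDipole(center + [-0.03, 0.01, -0.03], [1e-8, 0.0, 0.0])
        u1 = mt.sensor_reading(d1, sensors, center=center)
        u2 = mt.sensor_reading(d2, sensors, center=center)
        fs, T, freq = 100.0, 10.0, 5.0
        t = np.arange(int(fs * T)) / fs
        sig = np.outer(u1, np.sin(2 * np.pi * freq * t)) + np.outer(
            u2, np.sin(2 * np.pi * freq * t + np.pi / 2)
        )
        rec = mt.MultichannelRecording(sig, fs)
        decomp = mt.compute_spectrum(rec, 20.0)
        oscs = mt.extract_oscillations(decomp, decomp.freq_index(freq))
        assert len(oscs) == 2
        truths = [u1 / np.linalg.norm(u1), u2 / np.linalg.norm(u2)]
        for truth in truths:
            sims = [abs(o.pattern @ truth) for o in oscs]
            assert max(sims) > 0.99

    def test_split_components_conserve_energy(self, rng):
        for _ in range(50):
            d = random_row(rng, 8)
            rho2 = float(np.sum(d.cos_coeffs**2 + d.sin_coeffs**2))
            oscs = mt.extract_oscillations(d, 1, coherence_threshold=0.99)
            total = sum(o.energy for o in oscs)
            assert 0.0 <= total <= rho2 * (1 + 1e-6)

    def test_fastica_path_runs_or_falls_back(self, rng):
        d = random_row(rng, 8)
        oscs = mt.extract_oscillations(
            d, 1, coherence_threshold=0.999,
            ica=mt.ICASettings(method="fastica", seed=3),
        )
        assert 1 <= len(oscs) <= 2
        rho2 = float(np.sum(d.cos_coeffs**2 + d.sin_coeffs**2))
        assert sum(o.energy for o in oscs) <= rho2 * (1 + 1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_channel_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(1, 6))
        b = rng.normal(size=(1, 6))
        perm = rng.permutation(6)
        d1 = mt.SpectralDecomposition(
            frequencies=np.array([2.0]), cos_coeffs=a, sin_coeffs=b, duration=10.0
        )
        d2 = mt.SpectralDecomposition(
            frequencies=np.array([2.0]),
            cos_coeffs=a[:, perm],
            sin_coeffs=b[:, perm],
            duration=10.0,
        )
        assert mt.coherence(d1, 1) == pytest.approx(mt.coherence(d2, 1), abs=1e-12)
        o1 = mt.extract_oscillations(d1, 1)
        o2 = mt.extract_oscillations(d2, 1)
        assert len(o1) == len(o2)
        for x, y in zip(o1, o2):
            assert x.amplitude == pytest.approx(y.amplitude, rel=1e-9)
            assert np.allclose(np.abs(x.pattern[perm]), np.abs(y.pattern), atol=1e-9)


class TestSummaryPower:
    def test_single_tone_power(self):
        rec = tone_recording([[3.0]], [10.0], [0.0])
        d = mt.compute_spectrum(rec, 50.0)
        p = mt.summary_power_spectrum(d)
        n = d.freq_index(10.0)
        assert p[n - 1] == pytest.approx(9.0, rel=1e-9)
        assert np.delete(p, n - 1).max() < 1e-15

    def test_parseval_energy_identity(self, rng):
        fs, T = 100.0, 4.0
        data = rng.normal(size=(2, int(fs * T)))
        rec = mt.MultichannelRecording(data, fs)
        d = mt.compute_spectrum(rec, 50.0)
        spectral_energy = mt.summary_power_spectrum(d).sum() * T / 2.0
        spec = np.fft.rfft(data, axis=1)
        spec[:, 0] = 0.0
        spec[:, d.n_frequencies + 1 :] = 0.0
        band_limited = np.fft.irfft(spec, n=data.shape[1], axis=1)
        time_energy = np.sum(band_limited**2) / fs
        assert spectral_energy == pytest.approx(time_energy, rel=1e-6)

    def test_identical_channels_double_power(self):
        rec1 = tone_recording([[3.0]], [10.0], [0.0])
        rec2 = tone_recording([[3.0], [3.0]], [10.0], [0.0])
        p1 = mt.summary_power_spectrum(mt.compute_spectrum(rec1, 50.0))
        p2 = mt.summary_power_spectrum(mt.compute_spectrum(rec2, 50.0))
        assert np.allclose(p2, 2.0 * p1, rtol=1e-12, atol=1e-18)
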