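"""Wave-tube measurement chain: forcing, acoustics, estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oscivent as ov
from oscivent.signals_fot import (
    ImpedanceSpectrum,
    TransferFunction,
    _CGS_TO_CMH2O_S_L,
    default_component_grid,
)


class TestForcingSignal:
    def test_band_and_peak_to_peak(self, forcing):
        f = forcing
        assert f.component_freqs.min() >= 0.5
        assert f.component_freqs.max() <= 20.75
        assert np.isclose(f.samples.max() - f.samples.min(), 1.0, atol=1e-9)
        assert len(f.samples) == 8 * 256

    def test_components_mutually_non_harmonic(self, forcing):
        k = np.round(forcing.component_freqs / 0.25).astype(int)
        for i, ki in enumerate(k):
            for kj in k[:i]:
                assert ki % kj != 0

    def test_seeded_reproducibility(self):
        a = ov.make_forcing_signal(seed=5)
        b = ov.make_forcing_signal(seed=5)
        assert np.array_equal(a.samples, b.samples)
        c = ov.make_forcing_signal(seed=6)
        assert not np.array_equal(a.samples, c.samples)

    def test_single_component_is_pure_sine(self):
        f = ov.make_forcing_signal(band=(1.0, 1.0), peak_to_peak=1.0, seed=3)
        assert len(f.component_freqs) == 1 and f.component_freqs[0] == 1.0
        t = np.arange(len(f.samples)) / f.sample_rate
        expected = 0.5 * np.sin(2 * np.pi * 1.0 * t + f.component_phases[0])
        assert np.allclose(f.samples, expected, atol=1e-12)

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            ov.make_forcing_signal(band=(0.5, 200.0), sample_rate=256.0)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(p2p=st.floats(0.1, 10.0), seed=st.integers(0, 2**31 - 1))
    def test_peak_to_peak_normalization_property(self, p2p, seed):
        f = ov.make_forcing_signal(peak_to_peak=p2p, seed=seed)
        assert np.isclose(f.samples.max() - f.samples.min(), p2p, rtol=1e-9)


class TestTubeCoefficients:
    def test_lossless_limit(self, forcing):
        tube = ov.WaveTubeSpec(gas_viscosity=0.0)
        z0, gamma = ov.tube_coefficients(tube, forcing.component_freqs)
        rho_c_over_a = (
            tube.gas_density * tube.speed_of_sound / tube.area * _CGS_TO_CMH2O_S_L
        )
        assert np.allclose(np.abs(z0), rho_c_over_a, rtol=1e-12)
        assert np.allclose(gamma.real, 0.0, atol=1e-15)
        assert np.allclose(
            gamma.imag, 2 * np.pi * forcing.component_freqs / tube.speed_of_sound
        )

    def test_doubling_area_halves_z0_lossless(self):
        t1 = ov.WaveTubeSpec(gas_viscosity=0.0)
        t2 = ov.WaveTubeSpec(
            gas_viscosity=0.0, internal_diameter=t1.internal_diameter * np.sqrt(2)
        )
        f = np.array([5.0])
        z1, _ = ov.tube_coefficients(t1, f)
        z2, _ = ov.tube_coefficients(t2, f)
        assert np.isclose(np.abs(z1[0]) / np.abs(z2[0]), 2.0, rtol=1e-12)

    def test_lossy_line_attenuates(self, tube):
        _, gamma = ov.tube_coefficients(tube, np.array([0.5, 5.0, 20.75]))
        assert np.all(gamma.real > 0)

    def test_poiseuille_regime_against_symbolic_oracle(self, tube):
        """Independent high-precision evaluation of the RLC line formulas."""
        import sympy as sp

        f = 5.0
        a, mu, rho, c = (
            sp.Rational(375, 2000),
            sp.Float(tube.gas_viscosity, 30),
            sp.Float(tube.gas_density, 30),
            sp.Float(tube.speed_of_sound, 30),
        )
        area = sp.pi * a**2
        w = 2 * sp.pi * sp.Float(f, 30)
        zs = 8 * mu / (sp.pi * a**4) + sp.I * w * rho / area
        ys = sp.I * w * area / (rho * c**2)
        gamma_sym = sp.sqrt(zs * ys)
        z0_sym = sp.sqrt(zs / ys) * sp.Rational(1000) / sp.Float(980.665, 30)
        z0, gamma = ov.tube_coefficients(tube, np.array([f]))
        assert np.isclose(z0[0], complex(sp.N(z0_sym, 25)), rtol=1e-12)
        assert np.isclose(gamma[0], complex(sp.N(gamma_sym, 25)), rtol=1e-12)

    def test_nonpositive_geometry_rejected(self):
        with pytest.raises(ValueError):
            ov.WaveTubeSpec(internal_diameter=-1.0)
        with pytest.raises(ValueError):
            ov.tube_coefficients(ov.WaveTubeSpec(), np.array([0.0, 5.0]))


class TestTransferFunction:
    def test_identical_channels_give_unity(self, forcing):
        rec = ov.TimeSeriesRecording(p1=forcing.samples, p2=forcing.samples)
        tf = ov.transfer_function(rec, forcing.component_freqs)
        assert np.allclose(tf.values, 1.0 + 0j, atol=1e-12)

    def test_full_period_delay_has_unit_modulus(self, forcing):
        # delay by one full period of the 0.5 Hz component (512 samples)
        delayed = np.roll(forcing.samples, 512)
        rec = ov.TimeSeriesRecording(p1=forcing.samples, p2=delayed)
        tf = ov.transfer_function(rec, forcing.component_freqs)
        i = np.argmin(np.abs(tf.freqs - 0.5))
        assert np.isclose(np.abs(tf.values[i]), 1.0, rtol=1e-9)
        assert np.isclose(tf.values[i], 1.0 + 0j, atol=1e-9)

    def test_off_grid_component_rejected(self, forcing):
        rec = ov.TimeSeriesRecording(p1=forcing.samples, p2=forcing.samples)
        with pytest.raises(ValueError, match="FFT grid"):
            ov.transfer_function(rec, np.array([0.5, 1.03]))


class TestLoadImpedance:
    def test_matched_termination_returns_z0(self, tube):
        f = np.array([2.0, 5.0, 10.0])
        z0, gamma = ov.tube_coefficients(tube, f)
        tf = TransferFunction(freqs=f, values=np.exp(gamma * tube.length))
        z = ov.load_impedance(tf, tube)
        assert np.allclose(z.values, z0, rtol=1e-10)

    def test_round_trip_via_forward_two_port(self, tube):
        f = np.array([1.0, 3.0, 7.0, 15.0])
        z0, gamma = ov.tube_coefficients(tube, f)
        gl = gamma * tube.length
        zload = np.full(len(f), 10.0 + 3.0j)
        tf_values = np.cosh(gl) + (z0 / zload) * np.sinh(gl)
        z = ov.load_impedance(TransferFunction(freqs=f, values=tf_values), tube)
        assert np.allclose(z.values, zload, rtol=1e-9)

    def test_pole_frequency_dropped_with_warning(self, tube):
        f = np.array([2.0, 5.0])
        z0, gamma = ov.tube_coefficients(tube, f)
        gl = gamma * tube.length
        values = np.cosh(gl)  # open-end pole at both
        values[0] += (z0[0] / (10 + 3j)) * np.sinh(gl[0])  # make first valid
        with pytest.warns(RuntimeWarning, match="pole"):
            z = ov.load_impedance(TransferFunction(freqs=f, values=values), tube)
        assert len(z.freqs) == 1 and z.freqs[0] == 2.0

    def test_open_end_limit_grows(self, tube):
        f = np.array([5.0])
        z0, gamma = ov.tube_coefficients(tube, f)
        gl = gamma * tube.length
        zs = []
        for eps in (1e-3, 1e-6):
            tf = TransferFunction(freqs=f, values=np.cosh(gl) + eps)
            zs.append(np.abs(ov.load_impedance(tf, tube).values[0]))
        assert zs[1] > 100 * zs[0] / 1000  # grows as eps shrinks
        assert zs[1] > zs[0]


class TestSimulateAndRoundTrip:
    @pytest.mark.parametrize("load", ["baseline", "injured"])
    def test_round_trip_recovers_load(
        self, tube, forcing, baseline_params, injured_params, load
    ):
        params = baseline_params if load == "baseline" else injured_params
        z = ov.cpm_impedance(params, forcing.component_freqs)
        rec = ov.simulate_measurement(z, tube, forcing, noise_sd=0.0)
        tf = ov.transfer_function(rec, forcing.component_freqs)
        zhat = ov.load_impedance(tf, tube)
        rel = np.abs(zhat.values - z.values) / np.abs(z.values)
        assert rel.max() < 1e-6

    def test_estimate_invariant_to_forcing_amplitude(self, tube, baseline_params):
        zs = []
        for p2p in (1.0, 3.7):
            f = ov.make_forcing_signal(peak_to_peak=p2p, seed=1)
            z = ov.cpm_impedance(baseline_params, f.component_freqs)
            rec = ov.simulate_measurement(z, tube, f, noise_sd=0.0)
            zs.append(ov.load_impedance(ov.transfer_function(rec, f.component_freqs), tube))
        assert np.allclose(zs[0].values, zs[1].values, rtol=1e-9)

    def test_linearity_in_forcing(self, tube, forcing, baseline_params):
        z = ov.cpm_impedance(baseline_params, forcing.component_freqs)
        r1 = ov.simulate_measurement(z, tube, forcing, noise_sd=0.0)
        f2 = ov.make_forcing_signal(peak_to_peak=2.0, seed=1)
        r2 = ov.simulate_measurement(z, tube, f2, noise_sd=0.0)
        assert np.allclose(r2.p1, 2 * r1.p1, rtol=1e-9, atol=1e-12)
        assert np.allclose(r2.p2, 2 * r1.p2, rtol=1e-9, atol=1e-12)

    def test_noise_seeded(self, tube, forcing, baseline_params):
        z = ov.cpm_impedance(baseline_params, forcing.component_freqs)
        a = ov.simulate_measurement(z, tube, forcing, noise_sd=0.02, seed=9)
        b = ov.simulate_measurement(z, tube, forcing, noise_sd=0.02, seed=9)
        c = ov.simulate_measurement(z, tube, forcing, noise_sd=0.02, seed=10)
        assert np.array_equal(a.p1, b.p1) and np.array_equal(a.p2, b.p2)
        assert not np.array_equal(a.p1, c.p1)


class TestEnsembleAndInstrument:
    def _spec(self, values):
        return ImpedanceSpectrum(freqs=np.array([1.0, 2.0, 4.0]), values=values)

    def test_mean_of_two(self):
        a = self._spec(np.array([1 + 1j, 2 + 2j, 3 + 3j]))
        b = self._spec(np.array([3 - 1j, 4.0 + 0j, 5 - 3j]))
        avg = ov.ensemble_average([a, b])
        assert np.allclose(avg.values, (a.values + b.values) / 2)
        assert avg.n_averaged == 2

    def test_identical_spectra_unchanged(self):
        a = self._spec(np.array([1 + 1j, 2 + 2j, 3 + 3j]))
        avg = ov.ensemble_average([a, a, a])
        assert np.allclose(avg.values, a.values)

    def test_grid_mismatch_rejected(self):
        a = self._spec(np.zeros(3, dtype=complex) + 1)
        b = ImpedanceSpectrum(freqs=np.array([1.0, 2.0, 5.0]), values=np.ones(3) + 0j)
        with pytest.raises(ValueError, match="grid"):
            ov.ensemble_average([a, b])

    def test_averaging_shrinks_variance(self, tube, forcing, baseline_params):
        """Averaging k spectra cuts estimator variance ~k-fold (Monte-Carlo)."""
        z = ov.cpm_impedance(baseline_params, forcing.component_freqs)
        rng = np.random.default_rng(0)

        def estimate(n_rec, seed0):
            specs = [
                ov.load_impedance(
                    ov.transfer_function(
                        ov.simulate_measurement(z, tube, forcing, 0.02, seed0 + i),
                        forcing.component_freqs,
                    ),
                    tube,
                )
                for i in range(n_rec)
            ]
            return specs[0].values if n_rec == 1 else ov.ensemble_average(specs).values

        single = np.array([estimate(1, 1000 * r) for r in range(120)])
        avg4 = np.array([estimate(4, 1_000_000 + 1000 * r) for r in range(120)])
        v1 = np.var(single.real, axis=0).mean() + np.var(single.imag, axis=0).mean()
        v4 = np.var(avg4.real, axis=0).mean() + np.var(avg4.imag, axis=0).mean()
        assert 2.5 < v1 / v4 < 6.0  # ~4 within Monte-Carlo error

    def test_subtract_instrument(self, baseline_params, forcing):
        z = ov.cpm_impedance(baseline_params, forcing.component_freqs)
        instr = ImpedanceSpectrum(
            freqs=forcing.component_freqs,
            values=np.full(len(forcing.component_freqs), 5.0 + 1.0j),
        )
        total = ImpedanceSpectrum(
            freqs=forcing.component_freqs, values=z.values + instr.values
        )
        corrected = ov.subtract_instrument(total, instr)
        assert np.allclose(corrected.values, z.values)
        zero = ov.subtract_instrument(z, z)
        assert np.allclose(zero.values, 0.0)
        ident = ov.subtract_instrument(
            z,
            ImpedanceSpectrum(
                freqs=forcing.component_freqs,
                values=np.zeros(len(forcing.component_freqs), dtype=complex),
            ),
        )
        assert np.allclose(ident.values, z.values)


def test_default_grid_is_prime_multiples():
    grid = default_component_grid()
    assert grid[0] == 0.5 and grid[-1] == 20.75
    assert len(grid) == 23
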