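import numpy as np
import pytest
from scipy import stats as sps

import mpmri as m
from mpmri import models
from mpmri.grid import Grid

from conftest import build_phantom, homogeneous_modulus_phantom


class TestIRTrueFISP:
    def test_noiseless_frames_follow_closed_form_model(self, small_phantom):
        proto = m.ir_truefisp_protocol()
        stack = m.simulate_ir_truefisp(small_phantom, proto)
        ti = np.asarray(proto.inversion_times_ms)
        expected = np.abs(
            models.ir_truefisp_signal(
                ti[:, None, None],
                small_phantom.t1_ms[None],
                small_phantom.t2_ms[None],
                small_phantom.proton_density[None],
                proto.flip_deg,
            )
        )
        np.testing.assert_allclose(stack.frames, expected, rtol=0, atol=0)

    def test_long_inversion_time_approaches_steady_state(self, small_phantom):
        proto = m.ir_truefisp_protocol(
            inversion_times_ms=(30.0, 100.0, 300.0, 1000.0, 30000.0)
        )
        stack = m.simulate_ir_truefisp(small_phantom, proto)
        s_ss, _, _ = models.ir_truefisp_params(
            small_phantom.t1_ms, small_phantom.t2_ms,
            small_phantom.proton_density, proto.flip_deg,
        )
        np.testing.assert_allclose(stack.frames[-1], s_ss, rtol=1e-3)

    def test_nonpositive_relaxation_times_rejected(self):
        with pytest.raises(ValueError):
            models.ir_truefisp_signal(100.0, -5.0, 60.0, 1.0, 70.0)

    def test_rician_sample_mean_matches_closed_form(self):
        # single voxel value nu, 1e4 draws: sample mean within 3 SE of the
        # analytic Rician mean
        nu, sigma, n = 0.35, 0.1, 10_000
        rng = np.random.default_rng(42)
        draws = models.add_rician(np.full(n, nu), sigma, rng)
        expected = sps.rice.mean(b=nu / sigma, scale=sigma)
        se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - expected) < 3 * se

    @pytest.mark.parametrize("snr", [5.0, 20.0])
    def test_rician_variance_matches_formula(self, snr):
        nu, sigma, n = 1.0, 1.0 / snr, 10_000
        rng = np.random.default_rng(7)
        draws = models.add_rician(np.full(n, nu), sigma, rng)
        expected_var = sps.rice.var(b=nu / sigma, scale=sigma)
        assert abs(draws.var(ddof=1) - expected_var) / expected_var < 0.05


class TestMTPair:
    def test_on_off_arithmetic(self, small_phantom):
        stack = m.simulate_mt_pair(small_phantom, m.mt_rare_protocol())
        off, on = stack.frames
        viable = small_phantom.viable_mask
        np.testing.assert_allclose(on[viable], off[viable] * (1 - 0.30))

    def test_zero_attenuation_means_no_saturation(self):
        ph = build_phantom(mt_attenuation=0.0)
        ph = ph.with_fields(mt_attenuation=np.zeros_like(ph.mt_attenuation))
        stack = m.simulate_mt_pair(ph, m.mt_rare_protocol())
        np.testing.assert_array_equal(stack.frames[0], stack.frames[1])


class TestDWI:
    def test_closed_form_decay(self, small_phantom):
        stack = m.simulate_dwi(small_phantom, m.dwi_protocol())
        viable = small_phantom.viable_mask
        # ADC 800e-6 mm^2/s at b=1000 -> S0 * exp(-0.8)
        np.testing.assert_allclose(
            stack.frames[-1][viable], 1.0 * np.exp(-0.8), rtol=1e-12
        )

    def test_frames_strictly_decrease_with_b(self, hetero_phantom):
        stack = m.simulate_dwi(hetero_phantom, m.dwi_protocol())
        viable = hetero_phantom.viable_mask
        diffs = np.diff(stack.frames[:, viable], axis=0)
        assert np.all(diffs < 0)

    def test_out_of_range_b_rejected_by_protocol(self):
        with pytest.raises(ValueError):
            m.dwi_protocol(b_values=(0.0, 500.0, 1000.0))


class TestMGE:
    def test_closed_form_ratio(self, small_phantom):
        stack = m.simulate_mge(small_phantom, m.mge_protocol())
        viable = small_phantom.viable_mask
        ratio = stack.frames[-1][viable] / stack.frames[0][viable]
        np.testing.assert_allclose(ratio, np.exp(-30.0 * 0.021), rtol=1e-12)

    def test_zero_r2star_gives_flat_echo_train(self):
        ph = build_phantom(r2star_s=0.0)
        ph = ph.with_fields(r2star_s=np.zeros_like(ph.r2star_s))
        stack = m.simulate_mge(ph, m.mge_protocol())
        np.testing.assert_array_equal(stack.frames[0], stack.frames[-1])

    def test_log_signal_is_affine_in_te(self, small_phantom):
        stack = m.simulate_mge(small_phantom, m.mge_protocol())
        viable = small_phantom.viable_mask
        te_s = np.asarray(stack.frame_values) * 1e-3
        logs = np.log(stack.frames[:, viable])
        slopes = np.polyfit(te_s, logs, 1)[0]
        np.testing.assert_allclose(slopes, -30.0, rtol=1e-8)


class TestMREWavefield:
    def test_lossless_medium_has_constant_amplitude(self):
        ph = homogeneous_modulus_phantom(gd_kpa=5.0, gl_kpa=0.0)
        stack = m.simulate_mre_wavefield(ph, m.mre_protocol())
        wave = m.extract_harmonic(stack)
        amp = np.abs(wave.amplitude[0])
        np.testing.assert_allclose(amp, amp[0, 0], rtol=1e-12)

    def test_lossy_decay_matches_dispersion_relation(self):
        ph = homogeneous_modulus_phantom(gd_kpa=5.0, gl_kpa=2.0)
        stack = m.simulate_mre_wavefield(ph, m.mre_protocol())
        wave = m.extract_harmonic(stack)
        profile = np.abs(wave.amplitude[0, 32, :])
        k = models.shear_wavenumber(5000 + 2000j, 1000.0)
        h_m = wave.grid.spacing_mm * 1e-3
        predicted = profile[0] * np.exp(k.imag * h_m * np.arange(profile.size))
        np.testing.assert_allclose(profile, predicted, rtol=1e-9)

    def test_four_phase_dft_recovers_complex_amplitude_exactly(self):
        ph = homogeneous_modulus_phantom()
        stack = m.simulate_mre_wavefield(ph, m.mre_protocol())
        wave = m.extract_harmonic(stack)
        k = models.shear_wavenumber(5000 + 2000j, 1000.0)
        h_m = wave.grid.spacing_mm * 1e-3
        phi = k * h_m * (np.arange(wave.grid.nx) + 0.5)
        expected = 2e-5 * np.exp(-1j * phi)
        np.testing.assert_allclose(wave.amplitude[0, 10, :], expected, rtol=1e-9)

    def test_undersampled_wave_rejected(self):
        # very soft medium: wavelength < 4 voxels at 1 kHz on a coarse grid
        ph = homogeneous_modulus_phantom(gd_kpa=0.2, gl_kpa=0.0)
        with pytest.raises(ValueError, match="undersampled"):
            m.simulate_mre_wavefield(
                ph, m.mre_protocol(), mre_grid=Grid(32, 32, 19.2, 0.6, 3)
            )

    def test_discrete_helmholtz_residual_is_second_order(self):
        ph = homogeneous_modulus_phantom()
        k2 = (2 * np.pi * 1000.0) ** 2 * 1000.0 / (5000 + 2000j)
        rels = []
        for n in (64, 128):
            grid = Grid(n, n, 19.2, 0.3, 3)
            wave = m.extract_harmonic(
                m.simulate_mre_wavefield(ph, m.mre_protocol(), mre_grid=grid)
            )
            u = wave.amplitude[0]
            h = grid.spacing_mm * 1e-3
            lap = (
                u[2:, 1:-1] + u[:-2, 1:-1] + u[1:-1, 2:] + u[1:-1, :-2] - 4 * u[1:-1, 1:-1]
            ) / h**2
            resid = lap + k2 * u[1:-1, 1:-1]
            rels.append(np.abs(resid).max() / np.abs(k2 * u[1:-1, 1:-1]).max())
        assert rels[0] / rels[1] == pytest.approx(4.0, rel=0.15)


class TestDeterminism:
    @pytest.mark.parametrize(
        "factory,proto",
        [
            (m.simulate_ir_truefisp, m.ir_truefisp_protocol(noise_sigma=0.05, seed=3)),
            (m.simulate_dwi, m.dwi_protocol(noise_sigma=0.05, seed=3)),
            (m.simulate_mge, m.mge_protocol(noise_sigma=0.05, seed=3)),
            (m.simulate_mt_pair, m.mt_rare_protocol(noise_sigma=0.05, seed=3)),
            (m.simulate_mre_wavefield, m.mre_protocol(noise_sigma=0.05, seed=3)),
        ],
    )
    def test_fixed_seed_is_bit_reproducible(self, small_phantom, factory, proto):
        a = factory(small_phantom, proto)
        b = factory(small_phantom, proto)
        np.testing.assert_array_equal(a.frames, b.frames)
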