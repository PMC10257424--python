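import numpy as np
import pytest

import mpmri as m
from mpmri import fitting

from conftest import build_phantom


def _rel_err(est, truth, mask):
    return np.abs(est[mask] - truth[mask]) / np.abs(truth[mask])


class TestT1T2:
    def test_noiseless_round_trip_recovers_truth(self, hetero_phantom):
        ph = hetero_phantom
        t1, t2 = m.fit_t1_t2(m.simulate_ir_truefisp(ph, m.ir_truefisp_protocol()))
        roi = ph.viable_mask
        assert np.all(t1.valid_mask[roi])
        assert _rel_err(t1.values, ph.t1_ms, roi).max() < 1e-3
        assert _rel_err(t2.values, ph.t2_ms, roi).max() < 1e-3

    def test_constant_time_course_is_masked_invalid(self, small_phantom):
        stack = m.simulate_ir_truefisp(small_phantom, m.ir_truefisp_protocol())
        flat = np.ones_like(stack.frames)
        flat_stack = m.SignalStack(
            frames=flat,
            frame_axis=stack.frame_axis,
            frame_values=stack.frame_values,
            protocol=stack.protocol,
            grid=stack.grid,
        )
        t1, _ = m.fit_t1_t2(flat_stack)
        assert not t1.valid_mask.any()

    def test_snr50_median_t1_error_below_5pct(self):
        ph = build_phantom(heterogeneity=0.08, seed=21)
        proto = m.ir_truefisp_protocol(noise_sigma=0.02, seed=5)
        t1, _ = m.fit_t1_t2(m.simulate_ir_truefisp(ph, proto))
        roi = ph.viable_mask & t1.valid_mask
        assert roi.sum() > 50
        assert np.median(_rel_err(t1.values, ph.t1_ms, roi)) < 0.05

    def test_too_few_frames_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            m.ir_truefisp_protocol(inversion_times_ms=(50.0, 500.0, 3000.0))


class TestMTR:
    def test_arithmetic_and_identity_cases(self, small_phantom):
        mtr = m.compute_mtr(m.simulate_mt_pair(small_phantom, m.mt_rare_protocol()))
        viable = small_phantom.viable_mask
        np.testing.assert_allclose(mtr.values[viable], 30.0, rtol=1e-12)

    def test_zero_off_signal_is_invalid_not_exceptional(self, small_phantom):
        ph = small_phantom.with_fields(
            proton_density=np.zeros_like(small_phantom.proton_density)
        )
        mtr = m.compute_mtr(m.simulate_mt_pair(ph, m.mt_rare_protocol()))
        assert not mtr.valid_mask.any()

    def test_valid_mtr_is_bounded_under_noise(self, small_phantom):
        proto = m.mt_rare_protocol(noise_sigma=0.05, seed=2)
        mtr = m.compute_mtr(m.simulate_mt_pair(small_phantom, proto))
        vals = mtr.values[mtr.valid_mask]
        assert np.all(vals > -100.0) and np.all(vals <= 100.0)

    def test_missing_frame_label_rejected(self, small_phantom):
        stack = m.simulate_mt_pair(small_phantom, m.mt_rare_protocol())
        bad = m.SignalStack(
            frames=stack.frames,
            frame_axis="mt_state",
            frame_values=("off", "off2"),
            protocol=stack.protocol,
            grid=stack.grid,
        )
        with pytest.raises(ValueError, match="'off' and 'on'"):
            m.compute_mtr(bad)


class TestADC:
    def test_exact_log_linear_input(self, hetero_phantom):
        ph = hetero_phantom
        adc = m.fit_adc(m.simulate_dwi(ph, m.dwi_protocol()))
        roi = ph.viable_mask
        assert _rel_err(adc.values, ph.adc, roi).max() < 1e-9

    def test_flat_signal_gives_zero(self, small_phantom):
        ph = small_phantom.with_fields(adc=np.zeros_like(small_phantom.adc))
        adc = m.fit_adc(m.simulate_dwi(ph, m.dwi_protocol()))
        np.testing.assert_allclose(adc.values[adc.valid_mask], 0.0, atol=1e-9)

    def test_two_point_estimator_equals_closed_form(self, small_phantom):
        proto = m.dwi_protocol(b_values=(200.0, 1000.0))
        stack = m.simulate_dwi(small_phantom, proto)
        adc = m.fit_adc(stack)
        s1, s2 = stack.frames
        closed = np.log(s1 / s2) / (1000.0 - 200.0) * 1e6
        np.testing.assert_allclose(adc.values[adc.valid_mask], closed[adc.valid_mask])

    def test_snr40_roi_median_within_5pct(self, small_phantom):
        proto = m.dwi_protocol(noise_sigma=0.025, seed=9)
        adc = m.fit_adc(m.simulate_dwi(small_phantom, proto))
        roi = small_phantom.viable_mask & adc.valid_mask
        median = np.median(adc.values[roi])
        assert abs(median - 800.0) / 800.0 < 0.05

    def test_non_increasing_b_rejected(self, small_phantom):
        stack = m.simulate_dwi(small_phantom, m.dwi_protocol())
        bad = m.SignalStack(
            frames=stack.frames[::-1],
            frame_axis=stack.frame_axis,
            frame_values=stack.frame_values[::-1],
            protocol=stack.protocol,
            grid=stack.grid,
        )
        with pytest.raises(ValueError, match="increasing"):
            m.fit_adc(bad)


class TestR2star:
    def test_noiseless_decay_recovered_exactly(self, hetero_phantom):
        ph = hetero_phantom
        r2 = m.fit_r2star(m.simulate_mge(ph, m.mge_protocol()))
        roi = ph.viable_mask
        assert _rel_err(r2.values, ph.r2star_s, roi).max() < 1e-9

    def test_zero_rate_gives_zero(self, small_phantom):
        ph = small_phantom.with_fields(r2star_s=np.zeros_like(small_phantom.r2star_s))
        r2 = m.fit_r2star(m.simulate_mge(ph, m.mge_protocol()))
        np.testing.assert_allclose(r2.values[r2.valid_mask], 0.0, atol=1e-9)

    def test_truncated_train_matches_full_fit_on_clean_data(self):
        # fast decay: late echoes fall below an artificial floor and are
        # excluded; the truncated log-linear fit must match the full fit
        ph = build_phantom(r2star_s=150.0)
        stack = m.simulate_mge(ph, m.mge_protocol())
        full = m.fit_r2star(stack)
        floored = m.SignalStack(
            frames=stack.frames,
            frame_axis=stack.frame_axis,
            frame_values=stack.frame_values,
            protocol=stack.protocol,
            grid=stack.grid,
            provenance={"noise_sigma_abs": np.exp(-150.0 * 0.018) / fitting.FLOOR_FACTOR},
        )
        truncated = m.fit_r2star(floored)
        roi = ph.viable_mask & truncated.valid_mask
        assert roi.any()
        rel = np.abs(truncated.values[roi] - full.values[roi]) / full.values[roi]
        assert rel.max() < 0.01

    def test_nonlinear_method_agrees_on_clean_data(self, small_phantom):
        stack = m.simulate_mge(small_phantom, m.mge_protocol())
        lin = m.fit_r2star(stack)
        nonlin = m.fit_r2star(stack, method="nonlinear")
        roi = small_phantom.viable_mask
        np.testing.assert_allclose(nonlin.values[roi], lin.values[roi], rtol=1e-3)

    def test_too_few_echoes_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            m.mge_protocol(echo_times_ms=(3.0, 6.0))


class TestBiasPrecision:
    """At SNR 50 the ROI-median estimators are unbiased within 2% with CV < 10%."""

    @pytest.mark.parametrize(
        "simulate,proto_factory,fit,truth",
        [
            (m.simulate_dwi, m.dwi_protocol, m.fit_adc, 800.0),
            (m.simulate_mge, m.mge_protocol, lambda s: m.fit_r2star(s), 30.0),
            (m.simulate_mt_pair, m.mt_rare_protocol, m.compute_mtr, 30.0),
        ],
    )
    def test_roi_median_bias_and_cv_at_snr50(self, simulate, proto_factory, fit, truth):
        medians = []
        for seed in range(25):
            ph = build_phantom(seed=seed)
            proto = proto_factory(noise_sigma=0.02, seed=seed)
            pmap = fit(simulate(ph, proto))
            medians.append(m.roi_median(pmap, ph.viable_mask))
        medians = np.asarray(medians)
        assert abs(medians.mean() - truth) / truth < 0.02
        assert medians.std(ddof=1) / medians.mean() < 0.10
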