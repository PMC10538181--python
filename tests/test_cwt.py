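"""Streaming B-spline CWT: stage responses, oracle equivalence, fixed point."""

import numpy as np
import pytest

import splinecg as sc
from splinecg.cwt import (
    PREFILTER_FIXED,
    PREFILTER_FLOAT,
    CWTConfig,
    CWTProcessor,
    composed_kernel,
    cwt_reference,
    upsample_wavelet_taps,
)


class TestPrefilter:
    def test_float_weights_are_normalized_quintic_spline_samples(self):
        assert PREFILTER_FLOAT.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.array_equal(PREFILTER_FLOAT, PREFILTER_FLOAT[::-1])

    def test_fixed_impulse_response_is_the_printed_integer_row(self):
        p = CWTProcessor(CWTConfig(mode="fixed"))
        out = [p.prefilter_step(x) for x in [1, 0, 0, 0, 0, 0, 0]]
        assert out == [543, 14201, 36044, 14201, 543, 0, 0]

    def test_constant_input_passes_at_unit_gain_in_float_mode(self):
        p = CWTProcessor(CWTConfig(mode="float"))
        out = [p.prefilter_step(3.5) for _ in range(10)]
        assert out[-1] == pytest.approx(3.5, abs=1e-12)

    def test_zero_stream_stays_zero(self):
        p = CWTProcessor(CWTConfig())
        assert all(p.step(0.0) == 0.0 for _ in range(50))


class TestMovingSumCascade:
    def test_constant_input_reaches_dc_gain_m_to_the_fourth(self):
        m = 3
        p = CWTProcessor(CWTConfig(scale_m=m))
        out = [p.moving_sum_cascade_step(p.prefilter_step(1.0)) for _ in range(60)]
        assert out[-1] == pytest.approx(m**4, rel=1e-12)

    def test_matches_box_convolution_oracle(self, rng):
        """Four cascaded width-3 sums equal convolution with box^{*4}."""
        m = 3
        x = rng.normal(size=20)
        p = CWTProcessor(CWTConfig(scale_m=m))
        got = np.array([p.moving_sum_cascade_step(v) for v in x])
        box4 = np.ones(1)
        for _ in range(4):
            box4 = np.convolve(box4, np.ones(m))
        want = np.convolve(x, box4)[: len(x)]
        np.testing.assert_allclose(got, want, atol=1e-9)


class TestWaveletTaps:
    def test_scale_one_returns_base_taps(self):
        assert upsample_wavelet_taps(1).tolist() == [-1, -4, -5, 0, 5, 4, 1]

    def test_scale_three_matches_worked_example(self):
        want = [-1, 0, 0, -4, 0, 0, -5, 0, 0, 0, 0, 0, 5, 0, 0, 4, 0, 0, 1]
        assert upsample_wavelet_taps(3).tolist() == want

    @pytest.mark.parametrize("m", [1, 2, 5, 8, 16])
    def test_zero_mean_and_length(self, m):
        p_m = upsample_wavelet_taps(m)
        assert p_m.sum() == 0
        assert len(p_m) == 6 * m + 1

    def test_rejects_non_positive_scale(self):
        with pytest.raises(ValueError):
            upsample_wavelet_taps(0)

    def test_fir_impulse_response_equals_taps(self):
        m = 2
        p = CWTProcessor(CWTConfig(scale_m=m))
        imp = [1.0] + [0.0] * (6 * m)
        out = np.array([p.wavelet_fir_step(v) for v in imp])
        np.testing.assert_array_equal(out, upsample_wavelet_taps(m))

    def test_fir_constant_input_settles_to_zero(self):
        p = CWTProcessor(CWTConfig(scale_m=4))
        out = [p.wavelet_fir_step(2.0) for _ in range(60)]
        assert out[-1] == pytest.approx(0.0, abs=1e-12)


class TestComposedKernel:
    @pytest.mark.parametrize("m", [1, 2, 3, 4, 8, 16, 32])
    def test_length_zero_sum_and_antisymmetry(self, m):
        k = composed_kernel(CWTConfig(scale_m=m))
        assert len(k) == 10 * m + 1
        assert k.sum() == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(k, -k[::-1], atol=1e-12)

    def test_reference_is_linear(self, rng):
        cfg = CWTConfig(scale_m=4)
        x, y = rng.normal(size=(2, 200))
        lhs = cwt_reference(2.0 * x - 3.0 * y, cfg)
        rhs = 2.0 * cwt_reference(x, cfg) - 3.0 * cwt_reference(y, cfg)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestStreamingBatchEquivalence:
    @pytest.mark.parametrize("m", [2, 4, 8, 16])
    def test_streaming_equals_causal_convolution(self, m, rng):
        cfg = CWTConfig(scale_m=m)
        x = rng.normal(size=500)
        stream = CWTProcessor(cfg).process(x)
        batch = cwt_reference(x, cfg)[: len(x)]
        np.testing.assert_allclose(stream, batch, atol=1e-9)

    def test_constant_signal_settles_to_zero(self):
        p = CWTProcessor(CWTConfig(scale_m=8))
        out = [p.step(7.0) for _ in range(200)]
        assert out[-1] == pytest.approx(0.0, abs=1e-9)


class TestFixedPoint:
    def test_fidelity_on_adc_scaled_ecg(self, clean_record):
        _, signal, _ = clean_record
        counts = sc.mv_to_counts(signal[:15000])
        wf = CWTProcessor(CWTConfig(mode="fixed")).process(counts)
        wl = CWTProcessor(CWTConfig(mode="float")).process(counts.astype(float))
        dyn = wl.max() - wl.min()
        assert np.abs(wf - wl).max() / dyn <= 2**-10

    def test_full_scale_constant_raises_instead_of_wrapping(self):
        p = CWTProcessor(CWTConfig(mode="fixed"))
        with pytest.raises(sc.FixedPointOverflowError):
            for _ in range(200):
                p.step(2**23 - 1)

    def test_overflow_check_can_be_disabled(self):
        p = CWTProcessor(CWTConfig(mode="fixed", check_overflow=False))
        for _ in range(200):
            p.step(2**23 - 1)  # silently large, by explicit request


class TestConfig:
    @pytest.mark.parametrize(
        "kw", [{"scale_m": 0}, {"scale_m": 2.5}, {"fs_hz": 0}, {"mode": "int"},
               {"q_shift": -1}],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            CWTConfig(**kw)

    def test_reset_zeroes_all_registers(self, rng):
        p = CWTProcessor(CWTConfig(scale_m=4))
        p.process(rng.normal(size=100))
        p.reset()
        assert all(v == 0 for v in p.z)
        assert all(st.acc == 0 for st in p.stages)
        assert all(v == 0 for v in p.q)
        assert p.sample_index == 0


class TestLatency:
    def test_offset_constant_and_five_m_at_scale_8(self, clean_record):
        _, signal, truth = clean_record
        lat = sc.measure_latency(CWTConfig(scale_m=8), signal, truth["r_index"])
        assert lat == 5 * 8

    def test_offset_scales_with_m(self, clean_record):
        _, signal, truth = clean_record
        lat = sc.measure_latency(CWTConfig(scale_m=4), signal, truth["r_index"])
        assert lat == 5 * 4
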