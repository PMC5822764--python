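"""Tracer-parameter extraction from single time–intensity curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icgflow.kinetics import (
    IntensityCurve,
    KineticsConfig,
    estimate_baseline,
    extract_params,
    map_stack,
    REASON_CONSTANT,
    REASON_DEGENERATE_RISE,
)
from icgflow.io import FrameStack
from icgflow.simulate import CurveModelParams, model_curve

from oracles import fine_grid_moments

NO_FLOOR = KineticsConfig(noise_floor_sd=0.0)


def curve(times, values):
    return IntensityCurve(np.asarray(times, float), np.asarray(values, float))


class TestIntensityCurve:
    def test_rejects_length_mismatch_and_short_curves(self):
        with pytest.raises(ValueError):
            curve([0, 1, 2], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            curve([0, 1, 2], [1, 2, 3])

    def test_rejects_non_monotone_times_and_nonfinite(self):
        with pytest.raises(ValueError):
            curve([0, 2, 1, 3], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            curve([0, 1, 2, 3], [1, np.nan, 3, 4])


class TestBaseline:
    def test_flat_prebolus_segment_mean(self):
        est = estimate_baseline(curve([0, 1, 2, 3, 4], [10, 10, 10, 110, 60]))
        assert est.baseline == pytest.approx(10.0)
        assert est.provisional_onset_index == 3

    def test_constant_curve_flagged(self):
        est = estimate_baseline(curve([0, 1, 2, 3], [7, 7, 7, 7]))
        assert est.baseline == 7.0
        assert est.constant
        p = extract_params(curve([0, 1, 2, 3], [7, 7, 7, 7]))
        assert not p.valid and p.reason == REASON_CONSTANT

    def test_immediate_rise_falls_back_to_minimum(self):
        # first sample already above the provisional threshold
        est = estimate_baseline(curve([0, 1, 2, 3], [90, 50, 100, 95]))
        assert est.provisional_onset_index == 0
        assert est.baseline == 50.0

    def test_recovers_generator_baseline_exactly(self):
        # rise begins at frame 12 and crosses the provisional threshold
        # within one frame, so the baseline window is purely pre-bolus
        p = CurveModelParams(
            baseline=100.0, arrival=60.0, amplitude=1000.0,
            rise_time=20.0, washout_tau=120.0, plateau_fraction=0.3,
        )
        times = np.arange(120) * 5.0
        est = estimate_baseline(model_curve(p, times))
        assert est.baseline == pytest.approx(100.0, abs=1e-9)

    def test_dense_sampling_keeps_baseline_unbiased(self):
        # at dt = 0.1 many early-ramp samples precede the threshold
        # crossing; the median baseline must ignore them
        p = CurveModelParams(100.0, 60.0, 1000.0, 100.0, 120.0, 0.3)
        times = np.arange(0.0, 595.0, 0.1)
        est = estimate_baseline(model_curve(p, times))
        assert est.baseline == pytest.approx(100.0, abs=1e-9)


class TestExtractParams:
    def test_symmetric_triangle_mtt_at_apex(self):
        # flat pre-bolus segment, then a symmetric triangle: the first
        # moment of the net curve must sit at the apex
        t = np.arange(0.0, 116.0)
        apex = 60.0
        y = np.clip(100.0 - 2.0 * np.abs(t - apex), 0.0, None)
        p = extract_params(curve(t, y), NO_FLOOR)
        assert p.valid
        assert p.i_max == pytest.approx(100.0)
        assert p.peak_time == pytest.approx(apex, abs=0.5)
        assert p.mtt == pytest.approx(apex, abs=0.5)

    def test_rectangular_pulse_auc_approaches_area(self):
        dt = 0.01
        t = np.arange(0.0, 220.0, dt)
        y = np.where((t >= 100.0) & (t <= 120.0), 10.0, 0.0)
        p = extract_params(curve(t, y), NO_FLOOR)
        assert p.auc == pytest.approx(200.0, rel=2e-3)
        assert p.mtt == pytest.approx(110.0, abs=0.5)

    def test_degenerate_rise_flagged(self):
        # single-sample spike: onset and peak coincide
        y = [0, 0, 0, 0, 100, 0, 0, 0]
        p = extract_params(curve(range(8), y), NO_FLOOR)
        assert not p.valid and p.reason == REASON_DEGENERATE_RISE

    def test_noise_floor_rejects_sub_threshold_bumps(self):
        # pre-onset jitter of SD ~1: a net excursion of 3 (< 5 x SD) is
        # low-signal, a bolus of 50 (>> 5 x SD) is kept
        t = np.arange(120.0) * 5.0
        jitter = np.tile([1.0, -1.0], 60)  # sample SD ~1
        for height, expect_valid in ((3.0, False), (50.0, True)):
            y = 100.0 + jitter.copy()
            y[60:70] += height
            p = extract_params(curve(t, y), KineticsConfig(noise_floor_sd=5.0))
            assert p.valid == expect_valid, (height, p.reason)

    def test_mtt_onset_reference_shifts_by_onset(self):
        p = CurveModelParams(100.0, 60.0, 1000.0, 40.0, 120.0, 0.3)
        times = np.arange(120) * 5.0
        acq = extract_params(model_curve(p, times), NO_FLOOR)
        rel = extract_params(
            model_curve(p, times),
            KineticsConfig(noise_floor_sd=0.0, mtt_reference="onset"),
        )
        assert rel.mtt == pytest.approx(acq.mtt - acq.onset_time, rel=1e-12)


@pytest.mark.parametrize(
    "params",
    [
        CurveModelParams(100.0, 60.0, 1000.0, 40.0, 120.0, 0.4),
        CurveModelParams(50.0, 30.0, 5000.0, 100.0, 200.0, 0.1),
        CurveModelParams(0.0, 90.0, 800.0, 250.0, 300.0, 0.7),
    ],
)
class TestOracleEquivalence:
    """MTT/AUC against dense brute-force moments of the model function."""

    def test_dense_sampling_within_0p1_percent(self, params):
        window = 595.0
        times = np.arange(0.0, window + 0.05, 0.1)
        p = extract_params(model_curve(params, times), NO_FLOOR)
        mtt_o, auc_o = fine_grid_moments(params, window)
        assert p.mtt == pytest.approx(mtt_o, rel=1e-3)
        assert p.auc == pytest.approx(auc_o, rel=1e-3)

    def test_protocol_sampling_within_2_percent(self, params):
        times = np.arange(120) * 5.0
        p = extract_params(model_curve(params, times), NO_FLOOR)
        mtt_o, auc_o = fine_grid_moments(params, 595.0)
        assert p.mtt == pytest.approx(mtt_o, rel=0.02)
        assert p.auc == pytest.approx(auc_o, rel=0.02)


@st.composite
def random_model_params(draw):
    baseline = draw(st.floats(0.0, 500.0))
    arrival = draw(st.floats(15.0, 120.0))
    amplitude = draw(st.floats(200.0, 10000.0))
    rise_time = draw(st.floats(15.0, 300.0))
    tau = draw(st.floats(30.0, 500.0))
    rho = draw(st.floats(0.0, 0.9))
    return CurveModelParams(baseline, arrival, amplitude, rise_time, tau, rho)


class TestInvariants:
    @settings(max_examples=200, deadline=None)
    @given(random_model_params())
    def test_definitional_identity_bfi_times_trising(self, params):
        times = np.arange(120) * 5.0
        p = extract_params(model_curve(params, times), NO_FLOOR)
        if p.valid:
            assert abs(p.bfi * p.t_rising - p.i_max) <= 1e-9 * abs(p.i_max)
            assert p.onset_time <= p.peak_time
            assert 0 <= p.mtt <= times[-1]
            assert 0 <= p.auc <= p.i_max * times[-1]

    @settings(max_examples=50, deadline=None)
    @given(random_model_params(), st.floats(0.1, 50.0))
    def test_intensity_scaling_equivariance(self, params, c):
        times = np.arange(120) * 5.0
        base = model_curve(params, times)
        scaled = IntensityCurve(times, base.intensities * c)
        p0 = extract_params(base, NO_FLOOR)
        p1 = extract_params(scaled, NO_FLOOR)
        if not p0.valid:
            assert not p1.valid
            return
        assert p1.i_max == pytest.approx(c * p0.i_max, rel=1e-9)
        assert p1.bfi == pytest.approx(c * p0.bfi, rel=1e-9)
        assert p1.auc == pytest.approx(c * p0.auc, rel=1e-9)
        assert p1.onset_time == p0.onset_time
        assert p1.peak_time == p0.peak_time
        assert p1.t_rising == p0.t_rising
        assert p1.mtt == pytest.approx(p0.mtt, rel=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(random_model_params(), st.integers(1, 12))
    def test_time_shift_equivariance(self, params, k):
        # exact only for curves that decay fully inside the window
        # (otherwise the shift pushes tail mass past the last frame) and
        # whose pre-bolus plateau dominates the baseline window
        dt = 5.0
        times = np.arange(120) * dt
        params = CurveModelParams(
            params.baseline, params.arrival, params.amplitude,
            params.rise_time, params.washout_tau, 0.0,
        )
        shifted = CurveModelParams(
            params.baseline, params.arrival + k * dt, params.amplitude,
            params.rise_time, params.washout_tau, 0.0,
        )
        tail = times[-1] - shifted.arrival - shifted.rise_time
        if tail < 10.0 * params.washout_tau:
            return
        if params.arrival < 0.21 * params.rise_time + 2 * dt:
            return
        p0 = extract_params(model_curve(params, times), NO_FLOOR)
        p1 = extract_params(model_curve(shifted, times), NO_FLOOR)
        if not (p0.valid and p1.valid):
            return
        assert p1.onset_time == pytest.approx(p0.onset_time + k * dt, abs=1e-9)
        assert p1.peak_time == pytest.approx(p0.peak_time + k * dt, abs=1e-9)
        assert p1.i_max == pytest.approx(p0.i_max, rel=1e-9)
        assert p1.t_rising == pytest.approx(p0.t_rising, abs=1e-9)
        assert p1.bfi == pytest.approx(p0.bfi, rel=1e-9)
        assert p1.mtt - p0.mtt == pytest.approx(k * dt, abs=0.1)
        assert p1.auc == pytest.approx(p0.auc, rel=1e-3)


class TestMapStack:
    def test_broadcast_identity(self):
        p = CurveModelParams(100.0, 60.0, 1000.0, 40.0, 120.0, 0.3)
        times = np.arange(40) * 5.0
        y = model_curve(p, times).intensities
        frames = np.tile(y[:, None, None], (1, 4, 5))
        stack = FrameStack(frames, times, 0.5)
        mask = np.ones((4, 5), bool)
        pm = map_stack(stack, mask, NO_FLOOR)
        single = extract_params(model_curve(p, times), NO_FLOOR)
        assert pm.valid.all()
        assert np.allclose(pm["i_max"], single.i_max)
        assert np.allclose(pm["mtt"], single.mtt)

    def test_bimodal_amplitudes_recovered(self):
        times = np.arange(40) * 5.0
        pa = CurveModelParams(0.0, 30.0, 1000.0, 40.0, 120.0, 0.3)
        pb = CurveModelParams(0.0, 30.0, 500.0, 40.0, 120.0, 0.3)
        ya = model_curve(pa, times).intensities
        yb = model_curve(pb, times).intensities
        frames = np.empty((40, 2, 4))
        frames[:, 0, :] = ya[:, None]
        frames[:, 1, :] = yb[:, None]
        stack = FrameStack(frames, times, 0.5)
        pm = map_stack(stack, np.ones((2, 4), bool), NO_FLOOR)
        vals = np.unique(np.round(pm["i_max"], 6))
        assert np.allclose(sorted(vals), [500.0, 1000.0], atol=1e-6)

    def test_constant_stack_all_invalid(self, make_constant_stack):
        stack = make_constant_stack(7.0)
        pm = map_stack(stack, np.ones(stack.frame_shape, bool))
        assert not pm.valid.any()
        assert np.isnan(pm["i_max"]).all()
        assert pm.summary()["n_valid"] == 0

    def test_empty_mask_rejected(self, make_constant_stack):
        stack = make_constant_stack(7.0)
        with pytest.raises(ValueError):
            map_stack(stack, np.zeros(stack.frame_shape, bool))
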