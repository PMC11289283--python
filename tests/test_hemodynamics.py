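import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vascage.hemodynamics import (
    HRFModel,
    LocomotionEvents,
    build_design_matrix,
    deconvolve_hrf,
    detect_locomotion,
    fit_gamma_variate,
    hbt_oxy_regression,
    hrf_metrics,
    resting_periods,
    triggered_average,
)
from vascage.synthetic import (
    BehaviorTrace,
    events_to_delta,
    gamma_variate,
    generate_hemodynamics,
)

FS = 30.0


def make_events(intervals, duration_s=200.0, fs=FS):
    delta = events_to_delta(intervals, int(duration_s * fs), fs)
    return LocomotionEvents(delta=delta, fs_hz=fs, events=list(intervals))


class TestDetectLocomotion:
    def test_constant_velocity_no_events(self):
        t = np.arange(3000) / FS
        trace = BehaviorTrace(t, np.full_like(t, 4.0), FS)
        assert detect_locomotion(trace).events == []

    def test_ramp_above_threshold_single_event(self):
        fs = 100.0
        t = np.arange(int(20 * fs)) / fs
        v = np.clip((t - 2) * 5, 0, None) - np.clip((t - 6) * 5, 0, None)  # |a|=5 on [2,6]
        events = detect_locomotion(BehaviorTrace(t, v, fs))
        assert len(events.events) == 1
        onset, offset = events.events[0]
        assert abs(onset - 2.0) <= 2 / fs + 1e-9
        assert abs(offset - 6.0) <= 2 / fs + 1e-9

    def test_subthreshold_acceleration_ignored(self):
        fs = 100.0
        t = np.arange(int(30 * fs)) / fs
        v = 2.9 * t  # constant 2.9 cm/s² < 3 threshold
        assert detect_locomotion(BehaviorTrace(t, v, fs)).events == []

    def test_low_sampling_rate_rejected(self):
        t = np.arange(100) / 15.0
        with pytest.raises(ValueError, match="low"):
            detect_locomotion(BehaviorTrace(t, np.zeros_like(t), 15.0))


class TestRestingPeriods:
    def test_rule_arithmetic(self):
        # event ends at 10 s, next starts at 80 s: rest [14, 80] kept (66 s)
        rests = resting_periods([(5.0, 10.0), (80.0, 90.0)], duration_s=200.0)
        assert (14.0, 80.0) in rests

    def test_short_gap_dropped(self):
        # gap of 50 s leaves 46 s < 60 s
        rests = resting_periods([(5.0, 10.0), (60.0, 70.0)], duration_s=300.0)
        assert all(not (a >= 10 and b <= 60) for a, b in rests)

    def test_no_events_whole_trace_minus_lead(self):
        assert resting_periods([], duration_s=100.0) == [(4.0, 100.0)]
        assert resting_periods([], duration_s=50.0) == []


class TestTriggeredAverage:
    def test_identical_responses_zero_sem(self):
        fs = FS
        intervals = [(20.0, 30.0), (60.0, 70.0), (100.0, 110.0)]
        n = int(150 * fs)
        sig = np.zeros(n)
        for onset, _ in intervals:
            i = int(onset * fs)
            sig[i : i + 60] = np.linspace(0, 1, 60)
        ta = triggered_average(sig, fs, intervals, pre_s=2.0, post_s=5.0)
        assert ta.n_events == 3
        np.testing.assert_allclose(ta.sem, 0.0, atol=1e-12)

    def test_five_second_minimum_filter(self):
        intervals = [(20.0, 23.0), (60.0, 66.0)]  # 3 s and 6 s
        sig = np.zeros(int(100 * FS))
        ta = triggered_average(sig, FS, intervals, pre_s=1.0, post_s=2.0)
        assert ta.n_events == 1

    def test_no_qualifying_events_raises(self):
        with pytest.raises(ValueError, match="qualifying"):
            triggered_average(np.zeros(3000), FS, [(10.0, 12.0)], pre_s=1.0, post_s=2.0)

    def test_average_matches_kernel_convolved_step(self):
        # LTI synthetic response: onset-locked average equals kernel ⊛ step
        fs = FS
        intervals = [(30.0, 40.0), (90.0, 100.0), (150.0, 160.0)]
        ev = make_events(intervals, duration_s=220.0)
        traces, _ = generate_hemodynamics(ev, (1.0, 2.0, 1.5), kernel_s=8.0)
        ta = triggered_average(traces.hbt_um, fs, intervals, pre_s=1.0, post_s=6.0)
        k = int(8.0 * fs)
        kern = gamma_variate(np.arange(k + 1) / fs, 1.0, 2.0, 1.5)
        step = np.convolve(np.ones(int(6.0 * fs)), kern)[: int(6.0 * fs)]
        response = ta.mean[int(1.0 * fs) :]
        np.testing.assert_allclose(response, step[: response.size], atol=1e-9)


class TestDeconvolveHrf:
    def test_constant_signal_absorbed_by_intercept(self):
        ev = make_events([(20.0, 30.0)], duration_s=100.0)
        model = deconvolve_hrf(np.full(ev.delta.size, 7.0), ev, k_seconds=3.0)
        assert model.offset == pytest.approx(7.0, abs=1e-9)
        np.testing.assert_allclose(model.kernel[1:], 0.0, atol=1e-9)

    def test_noiseless_forward_model_recovered_exactly(self):
        rng = np.random.default_rng(8)
        n = int(400 * FS)
        delta = np.zeros(n)
        for onset in rng.uniform(20, 360, 12):
            i = int(onset * FS)
            delta[i : i + int(rng.uniform(2, 8) * FS)] = 1
        ev = LocomotionEvents(delta=delta, fs_hz=FS)
        k = int(10 * FS)
        h_true = np.concatenate([[0.7], gamma_variate(np.arange(1, k + 1) / FS, 0.5, 2.0, 1.6)])
        V = build_design_matrix(delta, k) @ h_true
        model = deconvolve_hrf(V, ev, k_seconds=10.0)
        np.testing.assert_allclose(model.kernel, h_true, atol=1e-9)

    def test_noisy_kernel_rmse_within_monte_carlo_bound(self):
        # bound frozen from a 40-run Monte-Carlo oracle at these settings
        rng = np.random.default_rng(1000)
        n = int(600 * FS)
        delta = np.zeros(n)
        for onset in rng.uniform(20, 560, 20):
            i = int(onset * FS)
            delta[i : i + int(rng.uniform(3, 8) * FS)] = 1
        ev = LocomotionEvents(delta=delta, fs_hz=FS)
        A, T, W = 0.55, 1.8, 1.5
        traces, _ = generate_hemodynamics(ev, (A, T, W), noise_sd=0.1 * A, seed=0)
        model = deconvolve_hrf(traces.hbt_um, ev)
        k = model.kernel.size - 1
        true_k = gamma_variate(np.arange(1, k + 1) / FS, A, T, W)
        rmse = np.sqrt(np.mean((model.kernel[1:] - true_k) ** 2))
        assert rmse < 0.03

    def test_residual_orthogonality(self):
        rng = np.random.default_rng(2)
        ev = make_events([(10.0, 16.0), (50.0, 60.0)], duration_s=120.0)
        V = rng.normal(size=ev.delta.size)
        model = deconvolve_hrf(V, ev, k_seconds=5.0)
        L = build_design_matrix(ev.delta, model.kernel.size - 1)
        resid = V - L @ model.kernel
        assert np.abs(L.T @ resid).max() < 1e-6

    def test_all_zero_events_rejected(self):
        ev = LocomotionEvents(delta=np.zeros(1000), fs_hz=FS)
        with pytest.raises(ValueError, match="unidentifiable"):
            deconvolve_hrf(np.zeros(1000), ev)

    def test_kernel_longer_than_signal_rejected(self):
        ev = make_events([(1.0, 2.0)], duration_s=5.0)
        with pytest.raises(ValueError, match="shorter"):
            deconvolve_hrf(np.zeros(ev.delta.size), ev, k_seconds=10.0)


class TestGammaVariate:
    @settings(derandomize=True, max_examples=40)
    @given(
        st.floats(0.1, 5.0),
        st.floats(0.3, 6.0),
        st.floats(0.2, 4.0),
    )
    def test_algebraic_identities(self, A, T, W):
        # peak value A at t=T, alpha*beta == T, zero at origin
        assert gamma_variate(T, A, T, W) == pytest.approx(A, abs=1e-12 * max(A, 1))
        alpha = (T / W) ** 2 * 8 * np.log(2)
        beta = W**2 / (T * 8 * np.log(2))
        assert alpha * beta == pytest.approx(T, rel=1e-12)
        assert gamma_variate(0.0, A, T, W) == 0.0

    def test_argmax_at_T_numerically(self):
        t = np.linspace(0, 20, 200001)
        y = gamma_variate(t, 1.3, 2.7, 1.1)
        assert t[np.argmax(y)] == pytest.approx(2.7, abs=1e-3)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gamma_variate(1.0, 1.0, -1.0, 1.0)


class TestFitGammaVariate:
    def test_noiseless_self_consistency(self):
        kern = gamma_variate(np.arange(1, 301) / FS, 1.0, 1.0, 1.0)
        fit = fit_gamma_variate(kern, FS)
        assert fit.A == pytest.approx(1.0, abs=1e-4)
        assert fit.T == pytest.approx(1.0, abs=1e-4)
        assert fit.W == pytest.approx(1.0, abs=1e-4)
        assert fit.r2 >= 0.9999

    def test_scaling_homogeneity(self):
        kern = gamma_variate(np.arange(1, 301) / FS, 0.8, 2.2, 1.4)
        f1 = fit_gamma_variate(kern, FS)
        f2 = fit_gamma_variate(3.0 * kern, FS)
        assert f2.A == pytest.approx(3.0 * f1.A, rel=1e-3)
        assert f2.T == pytest.approx(f1.T, rel=1e-3)
        assert f2.W == pytest.approx(f1.W, rel=1e-3)

    def test_noisy_kernel_within_monte_carlo_bound(self):
        # tolerance frozen from the seeded Monte-Carlo oracle run
        rng = np.random.default_rng(77)
        A, T, W = 0.55, 1.8, 1.5
        kern = gamma_variate(np.arange(1, 301) / FS, A, T, W)
        noisy = kern + rng.normal(0, 0.05 * A, kern.size)
        fit = fit_gamma_variate(noisy, FS)
        assert abs(fit.A - A) < 0.05
        assert abs(fit.T - T) < 0.15
        assert abs(fit.W - W) < 0.25

    def test_constant_kernel_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_gamma_variate(np.ones(100), FS)

    def test_stored_model_identities(self):
        kern = gamma_variate(np.arange(1, 301) / FS, 0.6, 2.5, 1.2)
        fit = fit_gamma_variate(kern, FS)
        assert fit.alpha * fit.beta == pytest.approx(fit.T, rel=1e-12)
        assert gamma_variate(fit.T, fit.A, fit.T, fit.W) == pytest.approx(fit.A, rel=1e-12)


class TestHrfMetrics:
    def test_amplitude_and_ttp(self):
        model = HRFModel(kernel=np.zeros(10), fs_hz=FS, A=1.0, T=1.0, W=1.0)
        amplitude, ttp, _ = hrf_metrics(model)
        assert amplitude == pytest.approx(1.0, rel=1e-6)
        assert ttp == pytest.approx(1.0, abs=2e-3)

    def test_fwhm_close_to_w_for_narrow_kernels(self):
        model = HRFModel(kernel=np.zeros(10), fs_hz=FS, A=1.0, T=4.0, W=1.5)  # T/W > 2
        _, _, fwhm = hrf_metrics(model)
        assert fwhm == pytest.approx(1.5, rel=0.10)

    def test_amplitude_linear_ttp_invariant_in_A(self):
        m1 = HRFModel(kernel=np.zeros(10), fs_hz=FS, A=1.0, T=2.0, W=1.0)
        m2 = HRFModel(kernel=np.zeros(10), fs_hz=FS, A=2.5, T=2.0, W=1.0)
        a1, t1, _ = hrf_metrics(m1)
        a2, t2, _ = hrf_metrics(m2)
        assert a2 == pytest.approx(2.5 * a1, rel=1e-9)
        assert t2 == pytest.approx(t1, abs=1e-9)


class TestEndToEndRecovery:
    def test_full_pipeline_recovers_planted_hrf(self):
        from vascage.synthetic import generate_locomotion_session

        fs = FS
        spec = [(30.0, 38.0), (90.0, 97.0), (150.0, 156.0), (210.0, 220.0), (280.0, 287.0)]
        trace, _ = generate_locomotion_session(360.0, fs, spec, noise_sd=0.0, seed=5)
        events = detect_locomotion(trace)
        A, T, W = 0.53, 1.9, 1.6
        traces, _ = generate_hemodynamics(events, (A, T, W), offset=0.4, noise_sd=0.0)
        model = deconvolve_hrf(traces.hbt_um, events)
        fit = fit_gamma_variate(model)
        assert fit.A == pytest.approx(A, rel=0.01)
        assert fit.T == pytest.approx(T, rel=0.01)
        assert fit.W == pytest.approx(W, rel=0.01)


class TestHbtOxyRegression:
    def test_exact_linear_relationship(self):
        fs = FS
        # varied durations so per-event response means span a range of x
        intervals = [
            (float(s), float(s + d))
            for s, d in zip(range(20, 260, 40), (2, 3, 4, 6, 8, 10))
        ]
        ev = make_events(intervals, duration_s=300.0)
        traces, _ = generate_hemodynamics(ev, (0.5, 2.0, 1.5), hbo_gain=1.5)
        oxy = traces.oxygenation_index()  # = 2 × response, so slope vs HbT is 2
        slope, intercept, r = hbt_oxy_regression(traces.hbt_um, oxy, intervals, fs)
        assert slope == pytest.approx(2.0, rel=1e-6)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_synthetic_line_recovered(self):
        rng = np.random.default_rng(4)
        fs = FS
        n = int(100 * fs)
        hbt = np.zeros(n)
        oxy = np.zeros(n)
        intervals = []
        for k, onset in enumerate(range(5, 95, 10)):
            x = rng.uniform(0.5, 2.0)
            i0, i1 = int((onset + 2) * fs), int((onset + 5) * fs)
            hbt[i0:i1] = x
            oxy[i0:i1] = 0.5 * x + 27.0
            intervals.append((float(onset), float(onset + 6)))
        slope, intercept, _ = hbt_oxy_regression(hbt, oxy, intervals, fs)
        assert slope == pytest.approx(0.5, rel=1e-9)
        assert intercept == pytest.approx(27.0, rel=1e-9)

    def test_single_event_rejected(self):
        with pytest.raises(ValueError, match="two events"):
            hbt_oxy_regression(np.ones(3000), np.ones(3000), [(10.0, 20.0)], FS)
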