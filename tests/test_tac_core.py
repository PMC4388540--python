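import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

from petquant.tac_core import (
    FrameSchedule,
    Kinetics2TC,
    LoganResult,
    TimeActivityCurve,
    _frame_average,
    finite_diff_derivative,
    forward_1tc,
    forward_2tc,
    read_tacs_csv,
    trapz_integral,
    write_tacs_csv,
)


def dense_schedule(span=60.0, dt=0.05):
    starts = np.arange(0.0, span, dt)
    return FrameSchedule(starts, np.full(starts.size, dt))


class TestFrameSchedule:
    def test_from_groups_default_protocol(self, schedule):
        assert schedule.F == 26
        assert schedule.span == pytest.approx(60.0)

    def test_single_frame_midpoint(self):
        s = FrameSchedule.from_groups([(1, 1.0)])
        assert s.F == 1
        assert s.midpoint[0] == pytest.approx(0.5)

    def test_total_duration(self):
        groups = [(4, 0.25), (2, 2.0), (3, 5.0)]
        s = FrameSchedule.from_groups(groups)
        assert s.span == pytest.approx(sum(c * d for c, d in groups))

    def test_rejects_overlap(self):
        with pytest.raises(ValueError, match="overlap"):
            FrameSchedule(np.array([0.0, 0.5]), np.array([1.0, 1.0]))

    def test_rejects_nonincreasing_starts(self):
        with pytest.raises(ValueError):
            FrameSchedule(np.array([0.0, 0.0]), np.array([1.0, 1.0]))

    def test_rejects_nonpositive_duration(self):
        with pytest.raises(ValueError):
            FrameSchedule(np.array([0.0]), np.array([0.0]))


class TestTimeActivityCurve:
    def test_length_mismatch(self, schedule):
        with pytest.raises(ValueError):
            TimeActivityCurve(schedule, np.ones(5))

    def test_nonfinite_rejected(self, schedule):
        v = np.ones(schedule.F)
        v[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            TimeActivityCurve(schedule, v)

    def test_plasma_must_be_nonnegative(self, schedule):
        v = np.ones(schedule.F)
        v[0] = -0.1
        with pytest.raises(ValueError, match="non-negative"):
            TimeActivityCurve(schedule, v, role="plasma")
        TimeActivityCurve(schedule, v, role="tissue")  # tissue may dip below 0

    def test_unknown_role(self, schedule):
        with pytest.raises(ValueError, match="role"):
            TimeActivityCurve(schedule, np.ones(schedule.F), role="venous")


class TestKinetics2TC:
    def test_derived_quantities(self):
        k = Kinetics2TC(0.25, 0.35, 0.05, 0.03)
        assert k.bp_nd == pytest.approx(5.0 / 3.0)
        assert k.dvr == pytest.approx(1 + 5.0 / 3.0)
        assert k.vt == pytest.approx((0.25 / 0.35) * (1 + 5.0 / 3.0))

    def test_alpha_ordering_and_roots(self):
        k = Kinetics2TC(0.25, 0.35, 0.05, 0.03)
        b = k.k2 + k.k3 + k.k4
        assert k.alpha1 <= k.alpha2
        assert k.alpha1 * k.alpha2 == pytest.approx(k.k2 * k.k4)
        assert k.alpha1 + k.alpha2 == pytest.approx(b)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            Kinetics2TC(-0.1, 0.2)


class TestTrapzIntegral:
    def test_constant_curve_unit_rectangle(self, schedule):
        tac = TimeActivityCurve(schedule, np.ones(schedule.F))
        # the (0, 0) initial node shaves half the first-midpoint sliver off
        # the exact rectangle area
        expected = 10.0 - schedule.midpoint[0] / 2.0
        assert trapz_integral(tac, 10.0) == pytest.approx(expected, abs=1e-12)
        assert trapz_integral(tac, 10.0) == pytest.approx(10.0, abs=schedule.midpoint[0])

    def test_zero_curve(self, schedule):
        tac = TimeActivityCurve(schedule, np.zeros(schedule.F))
        for T in (0.0, 5.0, 30.0, schedule.midpoint[-1]):
            assert trapz_integral(tac, T) == 0.0

    def test_linear_curve_closed_form(self):
        s = dense_schedule(span=10.0, dt=0.001)
        tac = TimeActivityCurve(s, s.midpoint.copy())
        assert trapz_integral(tac, 4.0) == pytest.approx(8.0, abs=1e-6)

    def test_range_errors(self, schedule):
        tac = TimeActivityCurve(schedule, np.ones(schedule.F))
        with pytest.raises(ValueError):
            trapz_integral(tac, -1.0)
        with pytest.raises(ValueError):
            trapz_integral(tac, schedule.midpoint[-1] + 1.0)

    @given(
        split=st.floats(min_value=1.0, max_value=50.0),
        upto=st.floats(min_value=51.0, max_value=57.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_additive_over_adjacent_intervals(self, split, upto):
        s = FrameSchedule.from_groups([(12, 10 / 60), (3, 1.0), (11, 5.0)])
        rng = np.random.default_rng(7)
        tac = TimeActivityCurve(s, rng.random(s.F) + 0.1)
        whole = trapz_integral(tac, upto)
        parts = trapz_integral(tac, split) + (whole - trapz_integral(tac, split))
        assert parts == pytest.approx(whole, rel=1e-12)
        # and explicitly: integral up to split plus integral of remainder
        assert trapz_integral(tac, split) <= whole + 1e-12


class TestFiniteDiffDerivative:
    def test_linear_curve(self):
        s = dense_schedule(span=10.0, dt=0.5)
        tac = TimeActivityCurve(s, 2.0 * s.midpoint)
        d = finite_diff_derivative(tac)
        assert np.allclose(d.values[1:-1], 2.0)
        assert d.role == "rate"

    def test_constant_curve(self, schedule):
        tac = TimeActivityCurve(schedule, np.full(schedule.F, 3.3))
        assert np.allclose(finite_diff_derivative(tac).values, 0.0)

    def test_exponential_matches_analytic(self):
        s = dense_schedule(span=5.0, dt=0.01)
        tac = TimeActivityCurve(s, np.exp(-s.midpoint))
        d = finite_diff_derivative(tac)
        expected = -np.exp(-s.midpoint)
        assert np.max(np.abs(d.values[1:-1] - expected[1:-1])) < 1e-3

    def test_spline_method_beats_central_on_coarse_grid(self, schedule):
        v = np.exp(-0.1 * schedule.midpoint)
        tac = TimeActivityCurve(schedule, v)
        truth = -0.1 * v
        e_central = np.max(np.abs(finite_diff_derivative(tac).values[2:-2] - truth[2:-2]))
        e_spline = np.max(
            np.abs(finite_diff_derivative(tac, method="spline").values[2:-2] - truth[2:-2])
        )
        assert e_spline < e_central

    def test_gcv_smoothing_denoises(self, schedule):
        rng = np.random.default_rng(0)
        clean = 5.0 * (1 - np.exp(-schedule.midpoint))
        noisy = clean + 0.1 * rng.standard_normal(schedule.F)
        tac = TimeActivityCurve(schedule, noisy)
        d_raw = finite_diff_derivative(tac, method="spline").values
        d_sm = finite_diff_derivative(tac, smoothing="gcv", method="spline").values
        truth = 5.0 * np.exp(-schedule.midpoint)
        assert np.mean((d_sm - truth) ** 2) < np.mean((d_raw - truth) ** 2)

    def test_too_few_frames(self):
        s = FrameSchedule.from_groups([(2, 1.0)])
        with pytest.raises(ValueError, match="3 frames"):
            finite_diff_derivative(TimeActivityCurve(s, np.ones(2)))

    def test_bad_method(self, schedule):
        tac = TimeActivityCurve(schedule, np.ones(schedule.F))
        with pytest.raises(ValueError, match="method"):
            finite_diff_derivative(tac, method="fourier")


class TestForwardModel:
    def test_zero_influx(self, schedule, aif_func):
        ct = forward_2tc(Kinetics2TC(0.0, 0.2, 0.1, 0.05), aif_func, schedule)
        assert np.all(ct.values == 0.0)

    def test_brief_bolus_matches_1tc_closed_form(self, schedule):
        # narrow Gaussian bolus (impulse-like): the convolution with the 1TC
        # kernel K1 e^{-k2 t} has the closed form below (normal CDF)
        from scipy.stats import norm

        K1, k2, mu, sig = 0.2, 0.2, 0.5, 0.05

        def bolus(t):
            return norm.pdf(t, loc=mu, scale=sig)

        def exact(t):
            t = np.asarray(t, dtype=float)
            return (
                K1
                * np.exp(-k2 * (t - mu) + 0.5 * k2**2 * sig**2)
                * norm.cdf((t - mu - k2 * sig**2) / sig)
            )

        ct = forward_1tc(K1, k2, bolus, schedule, dt_internal=0.005)
        expected = np.array(
            [quad(exact, s, s + d)[0] / d for s, d in zip(schedule.start, schedule.duration)]
        )
        assert np.max(np.abs(ct.values - expected)) < 1e-4

    def test_step_input_closed_form(self, schedule):
        K1, k2 = 0.2, 0.15
        ct = forward_1tc(K1, k2, lambda t: np.ones_like(t), schedule, dt_internal=0.01)

        def exact(u):
            return (K1 / k2) * (1 - np.exp(-k2 * u))

        expected = np.array(
            [quad(exact, s, s + d)[0] / d for s, d in zip(schedule.start, schedule.duration)]
        )
        assert np.max(np.abs(ct.values - expected)) < 1e-4

    def test_1tc_equals_2tc_with_zero_binding(self, schedule, aif_func):
        a = forward_1tc(0.3, 0.12, aif_func, schedule)
        b = forward_2tc(Kinetics2TC(0.3, 0.12, 0.0, 0.0), aif_func, schedule)
        assert np.array_equal(a.values, b.values)

    def test_matches_ode_oracle(self, schedule, aif_func):
        kin = Kinetics2TC(0.25, 0.35, 0.05, 0.03)
        ct = forward_2tc(kin, aif_func, schedule, dt_internal=0.01)

        def rhs(t, y):
            cp = aif_func(np.array([t]))[0]
            return [
                kin.K1 * cp - (kin.k2 + kin.k3) * y[0] + kin.k4 * y[1],
                kin.k3 * y[0] - kin.k4 * y[1],
            ]

        tt = np.linspace(0, 60, 12001)
        sol = solve_ivp(rhs, (0, 60), [0, 0], t_eval=tt, rtol=1e-10, atol=1e-13, method="LSODA")
        oracle = _frame_average(tt, sol.y.sum(axis=0), schedule)
        assert np.max(np.abs(ct.values - oracle)) / np.max(oracle) < 1e-3

    def test_linearity_in_input(self, schedule, aif_func):
        kin = Kinetics2TC(0.25, 0.3, 0.06, 0.04)
        a = forward_2tc(kin, aif_func, schedule)
        b = forward_2tc(kin, lambda t: 2.0 * aif_func(t), schedule)
        assert np.allclose(b.values, 2.0 * a.values, rtol=1e-10)

    def test_continuity_at_small_k3(self, schedule, aif_func):
        base = forward_2tc(Kinetics2TC(0.25, 0.3, 0.0, 0.1), aif_func, schedule)
        near = forward_2tc(Kinetics2TC(0.25, 0.3, 1e-6, 0.1), aif_func, schedule)
        assert np.max(np.abs(base.values - near.values)) < 1e-4 * np.max(base.values)

    def test_equilibrium_ratio_reaches_vt(self):
        kin = Kinetics2TC(0.3, 0.3, 0.05, 0.1)
        long = FrameSchedule.from_groups([(60, 5.0)])  # 300 minutes
        ct = forward_2tc(kin, lambda t: np.ones_like(t), long, dt_internal=0.05)
        assert ct.values[-1] == pytest.approx(kin.vt, rel=0.01)

    def test_degenerate_repeated_root(self, schedule, aif_func):
        # discriminant vanishes only for k3 = 0 with k2 = k4
        deg = forward_2tc(Kinetics2TC(0.2, 0.3, 0.0, 0.3), aif_func, schedule, dt_internal=0.01)
        ref = forward_1tc(0.2, 0.3, aif_func, schedule, dt_internal=0.01)
        # the repeated-root branch integrates with a plain trapezoid rule,
        # so it is first-order accurate near the bolus peak
        assert np.allclose(deg.values, ref.values, rtol=2e-3, atol=1e-4)

    def test_all_zero_rates_is_integrator(self, schedule, aif_func):
        ct = forward_2tc(Kinetics2TC(0.2, 0.0, 0.0, 0.0), aif_func, schedule, dt_internal=0.01)
        assert np.all(np.diff(ct.values) >= -1e-12)  # cumulative uptake

    def test_requires_blood_role_for_tac_input(self, schedule, aif_tac):
        tissue = TimeActivityCurve(schedule, aif_tac.values, role="tissue")
        with pytest.raises(ValueError, match="blood role"):
            forward_2tc(Kinetics2TC(0.2, 0.2), tissue)


class TestLoganResult:
    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            LoganResult(1.0, 0.0, (30, 60), 1, 1.0)


class TestCsvDialect:
    def test_round_trip(self, tmp_path, schedule, aif_tac):
        tacs = {
            "cerebellum": TimeActivityCurve(schedule, np.linspace(1, 2, schedule.F)),
            "plasma": aif_tac,
        }
        path = tmp_path / "tacs.csv"
        write_tacs_csv(path, tacs)
        back = read_tacs_csv(path)
        assert set(back) == {"cerebellum", "plasma"}
        assert back["plasma"].role == "plasma"
        assert back["cerebellum"].role == "tissue"
        assert np.allclose(back["plasma"].values, aif_tac.values)
        assert back["plasma"].schedule == schedule

    def test_missing_time_columns(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="frame_start_min"):
            read_tacs_csv(p)

    def test_mixed_schedules_rejected(self, tmp_path, schedule):
        other = FrameSchedule.from_groups([(4, 1.0)])
        with pytest.raises(ValueError, match="schedule"):
            write_tacs_csv(
                tmp_path / "x.csv",
                {
                    "a": TimeActivityCurve(schedule, np.ones(schedule.F)),
                    "b": TimeActivityCurve(other, np.ones(4)),
                },
            )
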