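import numpy as np
import pytest
from hypothesis import given, strategies as st

import patchkit as pk
from conftest import random_idealized


def ideal(levels, durations):
    return pk.IdealizedTrace(levels=levels, durations=durations)


class TestPopen:
    def test_quarter_open(self):
        tr = ideal([1, 0], [2.5, 7.5])
        res = pk.popen(tr, window_s=10.0)
        assert res.popen == pytest.approx(0.25)
        assert res.open_time_s + res.closed_time_s == pytest.approx(res.total_time_s)

    def test_never_open(self):
        res = pk.popen(ideal([0], [10.0]), window_s=10.0)
        assert res.popen == 0.0

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            pk.popen(ideal([0], [5.0]), window_s=10.0)

    def test_stationary_two_state_estimate(self):
        # Popen of a beta=30 / alpha=70 chain is beta/(alpha+beta) = 0.30
        model = pk.two_state_model(opening_rate=30.0, closing_rate=70.0)
        path = pk.simulate_gating(model, 0.0, 200.0, seed=8)
        est = pk.popen(path, window_s=200.0).popen
        se = np.sqrt(2 * 0.3 * 0.7 * (1 / 100.0) / 200.0)
        assert abs(est - 0.30) < 3 * se

    def test_estimator_bias_small_at_long_duration(self):
        # |bias| < 0.01 once T = 100 / min(alpha, beta)
        alpha, beta = 70.0, 30.0
        t_len = 100.0 / min(alpha, beta)
        model = pk.two_state_model(opening_rate=beta, closing_rate=alpha)
        vals = [
            pk.popen(pk.simulate_gating(model, 0.0, t_len, seed=s), window_s=t_len).popen
            for s in range(60)
        ]
        assert abs(np.mean(vals) - beta / (alpha + beta)) < 0.01


class TestPopenMulti:
    def test_two_channel_arithmetic(self):
        tr = ideal([1, 0], [4.0, 6.0])
        res = pk.popen_multi(tr, 2, window_s=10.0)
        assert res.popen == pytest.approx(0.2)

    def test_n1_reduces_to_single_channel_form(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tr = random_idealized(rng, max_level=1)
            w = tr.duration_s
            assert pk.popen_multi(tr, 1, window_s=w).popen == pytest.approx(
                pk.popen(tr, window_s=w).popen, rel=0, abs=0
            )

    def test_n_smaller_than_observed_level_rejected(self):
        tr = ideal([2, 0], [1.0, 9.0])
        with pytest.raises(ValueError, match="n_channels=1.*level 2"):
            pk.popen_multi(tr, 1, window_s=10.0)

    def test_binomial_patch_recovers_per_channel_popen(self):
        # N = 3 channels at per-channel p = 0.4
        model = pk.two_state_model(opening_rate=40.0, closing_rate=60.0, n_channels=3)
        path = pk.simulate_gating(model, 0.0, 100.0, seed=4)
        est = pk.popen_multi(path, 3, window_s=100.0).popen
        se = np.sqrt(2 * 0.4 * 0.6 * (1 / 100.0) / 100.0) / np.sqrt(3)
        assert abs(est - 0.4) < 3 * se


class TestLevelWeightedOpenTime:
    def test_worked_example(self):
        tr = ideal([1, 2, 0], [1.0, 0.5, 8.5])
        assert pk.level_weighted_open_time(tr) == pytest.approx(2.0)

    def test_all_closed_zero(self):
        assert pk.level_weighted_open_time(ideal([0], [3.0])) == 0.0

    def test_equals_channel_summed_open_time_on_two_channel_patch(self):
        # sum two independent single-channel paths into an aggregate and
        # check To(aggregate) == sum of the channels' individual open times
        paths = [
            pk.simulate_gating(pk.two_state_model(50.0, 50.0), 0.0, 5.0, seed=s)
            for s in (1, 2)
        ]
        edges = np.unique(np.concatenate(
            [np.cumsum(p.durations) for p in paths] + [[0.0]]
        ))
        mids = 0.5 * (edges[:-1] + edges[1:])

        def level_at(p, t):
            return p.levels[np.searchsorted(np.cumsum(p.durations), t, side="right")]

        agg = pk.IdealizedTrace(
            levels=level_at(paths[0], mids) + level_at(paths[1], mids),
            durations=np.diff(edges),
        )
        per_channel = sum(
            float(p.durations[p.levels == 1].sum()) for p in paths
        )
        assert pk.level_weighted_open_time(agg) == pytest.approx(per_channel, abs=1e-9)


class TestNpo:
    def test_single_channel_matches_popen(self):
        tr = ideal([1, 0], [2.5, 7.5])
        assert pk.npo(tr, window_s=10.0) == pytest.approx(0.25)

    def test_literal_formula_with_double_opening(self):
        # 1 s at level 2 + 9 s closed: To = 2, Tc = 9 -> NPo = 2/11
        tr = ideal([2, 0], [1.0, 9.0])
        assert pk.npo(tr, window_s=10.0) == pytest.approx(2.0 / 11.0)
        # strict per-sample alternative: fraction of time any channel open
        assert pk.npo(tr, window_s=10.0, strict_time_fraction=True) == pytest.approx(0.1)

    def test_adding_open_time_never_decreases_npo(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            tr = random_idealized(rng)
            base = pk.npo(tr, window_s=tr.duration_s)
            extended = pk.IdealizedTrace(
                levels=np.append(tr.levels, tr.levels[-1] + 1),
                durations=np.append(tr.durations, rng.exponential(0.1) + 1e-4),
            )
            assert pk.npo(extended, window_s=extended.duration_s) >= base - 1e-12


class TestNormalizePopen:
    def test_maps_max_to_one(self):
        normed, flag = pk.normalize_popen([0.1, 0.2, 0.4])
        assert normed == pytest.approx([0.25, 0.5, 1.0])
        assert flag is False

    def test_single_point(self):
        normed, _ = pk.normalize_popen([0.37])
        assert normed == pytest.approx([1.0])

    def test_all_zero_flagged_not_nan(self):
        normed, flag = pk.normalize_popen([0.0, 0.0])
        assert flag is True
        assert np.all(normed == 0.0)

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=20),
        st.floats(min_value=0.01, max_value=100.0),
    )
    def test_invariant_under_uniform_scaling(self, values, scale):
        a, _ = pk.normalize_popen(values)
        b, _ = pk.normalize_popen(np.asarray(values) * scale)
        assert a == pytest.approx(b)


class TestConductance:
    def test_exact_line_through_origin(self):
        v = np.arange(-100.0, 101.0, 20.0)
        iv = pk.fit_iv(v, 0.00965 * v * 10)  # i = 0.0965 pA/mV -> 96.5 pS
        assert iv.slope_ps == pytest.approx(96.5, abs=1e-9)
        assert iv.intercept_pa == pytest.approx(0.0, abs=1e-9)

    def test_two_point_conductance(self):
        iv = pk.fit_iv(np.array([-100.0, 100.0]), np.array([-5.72, 5.72]))
        assert iv.slope_ps == pytest.approx(57.2)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            v = rng.uniform(-100, 100, size=rng.integers(3, 12))
            i = rng.normal(0, 5, size=v.size)
            iv = pk.fit_iv(v, i)
            # closed-form OLS via the normal equations
            a = np.column_stack([v, np.ones_like(v)])
            beta = np.linalg.solve(a.T @ a, a.T @ i)
            assert iv.slope_ps == pytest.approx(beta[0] * 1e3)
            assert iv.intercept_pa == pytest.approx(beta[1])

    def test_limb_restricted_fit(self):
        v = np.arange(-100.0, 101.0, 20.0)
        i = np.where(v >= 0, 0.2 * v, 0.05 * v)  # rectifying
        g_out = pk.conductance(pk.IVCurve(v, i), fit_range_mv=(0.0, 100.0))
        g_in = pk.conductance(pk.IVCurve(v, i), fit_range_mv=(-100.0, 0.0))
        assert g_out == pytest.approx(200.0)
        assert g_in == pytest.approx(50.0)

    def test_single_voltage_rejected(self):
        with pytest.raises(ValueError, match="two distinct voltages"):
            pk.fit_iv(np.array([10.0, 10.0]), np.array([1.0, 1.1]))

    def test_nan_points_excluded(self):
        v = np.array([-100.0, 0.0, 100.0])
        i = np.array([-9.65, np.nan, 9.65])
        iv = pk.fit_iv(v, i)
        assert iv.slope_ps == pytest.approx(96.5)
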