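"""Windowed/daily CGM metric extraction against closed forms and oracles."""

import math
from datetime import date, datetime

import numpy as np
import pytest

from cgmdiet.metrics import (
    AnalysisWindow,
    DAILY_METRIC_NAMES,
    WINDOWED_METRIC_NAMES,
    auc_trapezoid,
    daily_metrics,
    extract_window,
    mage,
    peak_decomposition,
    windowed_metrics,
)
from conftest import make_trace, make_window


# --------------------------------------------------------------------------
# independent MAGE oracle: plateau-collapse, explicit extremum scan


def mage_oracle(glucose):
    g = [float(v) for v in glucose]
    sd = float(np.std(g, ddof=1))
    if sd == 0:
        return 0.0
    collapsed = [g[0]]
    for v in g[1:]:
        if v != collapsed[-1]:
            collapsed.append(v)
    if len(collapsed) < 2:
        return 0.0
    extrema = [collapsed[0]]
    for i in range(1, len(collapsed) - 1):
        prev, cur, nxt = collapsed[i - 1], collapsed[i], collapsed[i + 1]
        if (cur > prev and cur > nxt) or (cur < prev and cur < nxt):
            extrema.append(cur)
    extrema.append(collapsed[-1])
    signed = [b - a for a, b in zip(extrema, extrema[1:])]
    qualifying = [s for s in signed if abs(s) > sd]
    if not qualifying:
        return 0.0
    direction = math.copysign(1.0, qualifying[0])
    keep = [abs(s) for s in qualifying if math.copysign(1.0, s) == direction]
    return float(np.mean(keep))


class TestAUC:
    def test_constant_rectangle(self):
        t = np.arange(0, 121, 15.0)
        assert auc_trapezoid(t, np.full(t.size, 5.0)) == pytest.approx(600.0)

    def test_linear_ramp_closed_form(self):
        t = np.array([0.0, 30.0, 60.0])
        g = 4.0 + t / 30.0  # 4 -> 6 mmol/L over 60 min: area 300
        assert auc_trapezoid(t, g) == pytest.approx(300.0)

    def test_irregular_grid_matches_fine_riemann_on_smooth_trace(self):
        rng = np.random.default_rng(3)
        t = np.sort(np.concatenate([[0.0, 240.0], rng.uniform(0, 240, 40)]))
        f = lambda x: 5.0 + 1.2 * np.sin(2 * np.pi * x / 240.0)  # noqa: E731
        coarse = auc_trapezoid(t, f(t))
        fine_t = np.arange(0.0, 240.0, 1.0) + 0.5
        riemann = float(np.sum(f(fine_t)))
        assert coarse == pytest.approx(riemann, rel=0.01)

    def test_single_reading_is_an_error(self):
        with pytest.raises(ValueError):
            auc_trapezoid([0.0], [5.0])


class TestPeakDecomposition:
    def test_two_bumps_peak_on_taller(self):
        t = np.arange(0, 9) * 15.0
        g = np.array([5.0, 6.0, 7.0, 6.0, 5.0, 6.5, 8.0, 6.5, 5.0])
        # brute-force: interior samples strictly above both neighbors
        interior = [i for i in range(1, 8) if g[i] > g[i - 1] and g[i] > g[i + 1]]
        best = max(interior, key=lambda i: g[i])
        pk = peak_decomposition(t, g)
        assert pk.peak_time == t[best] and pk.peak_value == g[best] == 8.0

    def test_monotone_window_falls_back_to_global_max_with_zero_fall(self):
        t = np.arange(0, 5) * 15.0
        g = np.array([4.0, 4.5, 5.0, 5.5, 6.0])
        pk = peak_decomposition(t, g)
        assert pk.peak_time == t[-1]
        assert pk.trough_time == t[-1]  # window-end fallback: t_fall = 0

    def test_trough_is_first_local_min_after_global_max(self):
        t = np.arange(0, 7) * 10.0
        g = np.array([5.0, 8.0, 6.0, 6.5, 6.0, 7.0, 6.8])
        pk = peak_decomposition(t, g)
        assert pk.global_max_time == 10.0
        assert pk.trough_time == 20.0 and pk.trough_value == 6.0


class TestWindowedMetrics:
    def test_triangular_bump_hand_values(self):
        win = make_window([0, 30, 60, 90, 120], [5.0, 6.0, 7.0, 6.0, 5.0])
        mv = windowed_metrics(win)
        assert mv.amp == pytest.approx(2.0)
        assert mv.t_rise == pytest.approx(60.0)
        assert mv.t_fall == pytest.approx(60.0)
        assert mv.slope_rise == pytest.approx(1 / 30)
        assert mv.slope_fall == pytest.approx(-1 / 30)
        assert mv.slope_ratio == pytest.approx(1.0)
        assert mv.auc == pytest.approx(720.0)
        assert mv.auc_rise == pytest.approx(360.0)
        assert mv.auc_fall == pytest.approx(360.0)
        assert mv.amp_min == pytest.approx(5.0)
        assert mv.slope_steepest == pytest.approx(1 / 30)

    def test_constant_window_degenerate_conventions(self):
        win = make_window(np.arange(0, 121, 15.0), np.full(9, 5.5))
        mv = windowed_metrics(win)
        assert mv.amp == 0 and mv.sd == 0 and mv.var == 0 and mv.mage == 0 and mv.cv == 0
        for name in ("slope_rise", "slope_fall", "slope_avg", "slope_steepest", "slope_ratio"):
            assert getattr(mv, name) == 0.0
        assert math.isnan(mv.skew) and math.isnan(mv.kurtosis)

    def test_moment_identities(self):
        rng = np.random.default_rng(7)
        g = 5.0 + rng.normal(0, 0.6, 17).cumsum() * 0.1 + rng.uniform(0, 1, 17)
        g = np.abs(g) + 1.0
        win = make_window(np.arange(17) * 15.0, g)
        mv = windowed_metrics(win)
        assert mv.var == mv.sd**2
        assert mv.cv == pytest.approx(100 * mv.sd / mv.mean)
        assert mv.amp_min <= mv.mean

    def test_shift_invariance(self):
        rng = np.random.default_rng(11)
        t = np.arange(16) * 15.0
        g = 5.0 + np.abs(rng.normal(0, 1, 16))
        a, b = windowed_metrics(make_window(t, g)), windowed_metrics(make_window(t, g + 2.5))
        for name in ("sd", "var", "mage", "amp", "slope_rise", "slope_fall",
                     "slope_avg", "slope_steepest", "t_rise", "t_fall"):
            va, vb = getattr(a, name), getattr(b, name)
            assert va == pytest.approx(vb, nan_ok=True)
        assert b.mean == pytest.approx(a.mean + 2.5)
        assert b.auc == pytest.approx(a.auc + 2.5 * (t[-1] - t[0]))

    def test_auc_partitions_on_clean_single_peak(self):
        t = np.arange(0, 13) * 15.0
        g = 5.0 + 2.0 * np.exp(-((t - 60.0) ** 2) / (2 * 30.0**2))
        win = make_window(t, g)
        mv = windowed_metrics(win)
        pk = peak_decomposition(t, g)
        tail = (t >= pk.trough_time)
        remainder = float(np.trapezoid(g[tail], t[tail])) if tail.sum() >= 2 else 0.0
        assert mv.auc == pytest.approx(mv.auc_rise + mv.auc_fall + remainder)

    def test_metric_vector_has_exactly_19_named_metrics(self):
        assert len(WINDOWED_METRIC_NAMES) == 19
        win = make_window([0, 30, 60, 90, 120], [5.0, 6.0, 7.0, 6.0, 5.0])
        assert tuple(windowed_metrics(win).as_dict()) == WINDOWED_METRIC_NAMES


class TestMAGE:
    def test_constant_trace_zero(self):
        assert mage(np.arange(5) * 15.0, np.full(5, 5.0)) == 0.0

    def test_square_wave_excursions(self):
        g = np.array([4.0, 8.0, 4.0, 8.0, 4.0, 8.0, 4.0])
        assert mage(np.arange(7) * 15.0, g) == pytest.approx(4.0)

    def test_subthreshold_excursion_ignored(self):
        g = np.array([5.0, 5.5, 5.0, 8.0, 5.0])  # sd ~ 1.3; only the 3.0 swings count
        sd = g.std(ddof=1)
        result = mage(np.arange(5) * 15.0, g)
        assert result == pytest.approx(3.0)
        assert 0.5 < sd < 3.0

    def test_matches_independent_oracle_on_random_traces(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(8, 40))
            g = 5.0 + np.round(rng.normal(0, 0.8, n).cumsum(), 2)
            g = np.abs(g) + 1.0
            got = mage(np.arange(n) * 5.0, g)
            assert got == pytest.approx(mage_oracle(g), rel=1e-12, abs=1e-12)


class TestExtractWindow:
    def test_full_coverage_returns_all_samples(self):
        t = np.arange(0, 24 * 60, 15.0)
        tr = make_trace(t, np.full(t.size, 5.0))
        win = extract_window(tr, AnalysisWindow(datetime(2024, 3, 4, 8), 2.0))
        assert win.sufficient and win.glucose.size == 9

    def test_empty_window_insufficient(self):
        tr = make_trace(np.arange(0, 60, 15.0), np.full(4, 5.0))
        win = extract_window(tr, AnalysisWindow(datetime(2024, 3, 6, 8), 2.0))
        assert not win.sufficient and win.glucose.size == 0

    def test_sparse_window_flagged_by_coverage_rule(self):
        # 3 of the 9 expected samples in a 2 h window at 15-min cadence
        t = np.array([0.0, 15.0, 120.0])
        tr = make_trace(t + 8 * 60, np.full(3, 5.0))
        win = extract_window(tr, AnalysisWindow(datetime(2024, 3, 4, 8), 2.0), min_coverage=0.8)
        assert not win.sufficient
        assert win.coverage == pytest.approx(3 / 9)


class TestDailyMetrics:
    def test_constant_day(self):
        t = np.arange(0, 24 * 60, 15.0)
        tr = make_trace(t, np.full(t.size, 5.3))
        met = daily_metrics(tr, date(2024, 3, 4))
        assert met is not None
        assert met["mean"] == pytest.approx(5.3)
        assert met["sd"] == pytest.approx(0.0, abs=1e-12)
        assert tuple(met) == DAILY_METRIC_NAMES and len(met) == 6

    def test_var_is_sd_squared_each_day(self, small_cohort):
        tr = next(iter(small_cohort.traces.values()))
        d = tr.times[0].astype("datetime64[D]").astype(object)
        met = daily_metrics(tr, d)
        assert met is not None and met["var"] == met["sd"] ** 2

    def test_undersampled_day_excluded(self):
        t = np.arange(0, 6 * 60, 15.0)  # quarter of a day only
        tr = make_trace(t, np.full(t.size, 5.0))
        assert daily_metrics(tr, date(2024, 3, 4)) is None
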