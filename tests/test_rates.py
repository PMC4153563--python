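import numpy as np
import pytest

from hapalysis import (
    FeatureLabel,
    FeaturePoint,
    HormoneSeries,
    RiseFallSegment,
    compute_rates,
    extract_segments,
    fit_rate_regression,
    multiscale_summary,
    run_hap,
)

from conftest import make_series, random_sim_series


def seg(level, nadir_a, peak, nadir_b):
    def fp(t, v, lab):
        return FeaturePoint(int(t), float(t), float(v), lab)

    return RiseFallSegment(
        level,
        fp(*nadir_a, FeatureLabel.N),
        fp(*peak, FeatureLabel.P),
        fp(*nadir_b, FeatureLabel.N),
    )


class TestSegmentArithmetic:
    def test_single_segment_rates(self):
        s = seg(1, (0, 1), (10, 5), (20, 2))
        assert s.rise_duration == 10 and s.fall_duration == 10
        assert s.rise_amplitude == 4 and s.fall_amplitude == 3
        assert s.accumulation_rate == pytest.approx(0.4)
        assert s.dissipation_rate == pytest.approx(0.3)
        assert s.internadir_interval == 20

    def test_micro_example_segments(self, micro_series):
        hap = run_hap(micro_series)
        segs = extract_segments(hap, 1)
        assert [s.internadir_interval for s in segs] == [20, 20]
        assert segs[1].accumulation_rate == pytest.approx(0.4)

    def test_m_nadirs_give_m_minus_one_segments(self):
        # 5 nadirs at level 1 -> exactly 4 of each rate and 4 intervals
        s = make_series([1, 5, 2, 6, 1, 7, 3, 8, 2])
        hap = run_hap(s)
        assert len(hap.levels[0].nadirs) == 5
        table = compute_rates(extract_segments(hap, 1))
        assert len(table) == 4

    def test_level_without_two_nadirs_is_empty(self):
        hap = run_hap(make_series([5, 4, 3, 2, 1]))
        assert extract_segments(hap, 1) == []


class TestConservation:
    @pytest.mark.parametrize("seed", range(10))
    def test_telescoping_rise_minus_fall(self, seed):
        hap = run_hap(random_sim_series(6000 + seed))
        for lv in hap.levels:
            segs = extract_segments(hap, lv.level)
            if not segs:
                continue
            net = sum(s.rise_amplitude for s in segs) - sum(
                s.fall_amplitude for s in segs
            )
            expected = lv.nadirs[-1].value - lv.nadirs[0].value
            assert net == pytest.approx(expected, abs=1e-9)

    def test_time_rescaling_divides_rates(self):
        vals = [1, 5, 2, 6, 1, 7, 3]
        a = compute_rates(extract_segments(run_hap(make_series(vals, 10.0)), 1))
        b = compute_rates(extract_segments(run_hap(make_series(vals, 30.0)), 1))
        assert np.allclose(b["accumulation_rate"], a["accumulation_rate"] / 3)
        assert np.allclose(b["dissipation_rate"], a["dissipation_rate"] / 3)
        assert np.allclose(b["internadir_interval"], a["internadir_interval"] * 3)

    def test_value_shift_leaves_rates_unchanged(self):
        vals = np.array([1, 5, 2, 6, 1, 7, 3], dtype=float)
        a = compute_rates(extract_segments(run_hap(make_series(vals)), 1))
        b = compute_rates(extract_segments(run_hap(make_series(vals + 11)), 1))
        assert np.allclose(a["accumulation_rate"], b["accumulation_rate"])
        assert np.allclose(a["internadir_interval"], b["internadir_interval"])


def ols_normal_equations(x, y):
    """Closed-form simple OLS oracle: slope and intercept."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxx = n * np.sum(x * x) - np.sum(x) ** 2
    slope = (n * np.sum(x * y) - np.sum(x) * np.sum(y)) / sxx
    intercept = (np.sum(y) - slope * np.sum(x)) / n
    return slope, intercept


class TestRegression:
    def _segments(self, durations, amplitudes):
        out = []
        t = 0.0
        for d, a in zip(durations, amplitudes):
            out.append(seg(1, (t, 0.0), (t + d, a), (t + d + 10, 0.0)))
            t += d + 20
        return out

    def test_perfect_fit_recovers_slope(self):
        segs = self._segments([10, 20, 30, 40], [2, 4, 6, 8])
        r = fit_rate_regression(segs, "rise")
        assert r.slope == pytest.approx(0.2)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)
        assert r.r2 == pytest.approx(1.0)

    def test_noisy_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        durations = np.repeat([10.0, 20.0, 30.0], 4)
        amplitudes = 0.25 * durations + rng.normal(0, 0.5, size=12)
        segs = self._segments(durations, np.abs(amplitudes))
        r = fit_rate_regression(segs, "rise")
        slope, intercept = ols_normal_equations(
            durations, [s.rise_amplitude for s in segs]
        )
        assert r.slope == pytest.approx(slope)
        assert r.intercept == pytest.approx(intercept)
        assert r.ci95[0] < slope < r.ci95[1]

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        durations = rng.choice([10.0, 20.0, 30.0, 40.0], size=8)
        amps = 0.2 * durations + rng.normal(0, 0.3, size=8)
        segs = self._segments(durations, np.abs(amps))
        a = fit_rate_regression(segs, "rise")
        b = fit_rate_regression(segs[::-1], "rise")
        assert a.slope == pytest.approx(b.slope)
        assert a.r2 == pytest.approx(b.r2)

    def test_under_three_segments_slope_only(self):
        segs = self._segments([10, 20], [2, 5])
        r = fit_rate_regression(segs, "fall")
        assert r.ci95 is None and r.r2 is None and r.n == 2
        assert np.isfinite(r.slope)

    def test_rise_and_fall_use_their_own_sides(self):
        segs = [seg(1, (0, 1), (10, 5), (50, 1)), seg(1, (50, 1), (70, 9), (120, 2)),
                seg(1, (120, 2), (130, 6), (180, 1))]
        rise = fit_rate_regression(segs, "rise")
        fall = fit_rate_regression(segs, "fall")
        assert rise.slope != pytest.approx(fall.slope)


class TestMultiscale:
    def test_single_pulse_summary_matches_compute_rates(self):
        hap = run_hap(make_series([1, 3, 1]))
        table = multiscale_summary(hap)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["rise_duration_min"] == row["rise_duration_median"] == 10

    def test_median_of_two_is_their_mean(self):
        s = make_series([1, 5, 2, 6, 1])
        table = multiscale_summary(run_hap(s))
        lvl1 = table[table["level"] == 1].iloc[0]
        assert lvl1["n_segments"] == 2
        assert lvl1["rise_amplitude_median"] == pytest.approx((4 + 4) / 2)

    def test_interval_medians_reported_in_hours(self, validation_parses):
        _, _, hap = validation_parses[1.0]
        table = multiscale_summary(hap)
        assert np.allclose(
            table["internadir_interval_median_h"] * 60,
            table["internadir_interval_median"],
        )
        assert table["internadir_interval_median"].is_monotonic_increasing
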