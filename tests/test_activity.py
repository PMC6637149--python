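"""Activity reduction: calibration fits, linear-range search against an
exhaustive oracle, unit conversion, and replicate summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nitkit import activity as act
from nitkit import synthetic


def make_series(times, absorbances, mass=0.001):
    return act.ActivitySeries(
        times_s=np.asarray(times, float),
        absorbances=np.asarray(absorbances, float),
        enzyme_mg=mass,
    )


class TestCalibration:
    def test_exact_line_recovered(self):
        standards = [(x, 0.01 * x) for x in (0.0, 10.0, 20.0, 50.0)]
        cal = act.fit_calibration(standards)
        assert cal.slope == pytest.approx(0.01, rel=1e-12)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)
        assert cal.r2 == pytest.approx(1.0)

    def test_noisy_fit_matches_normal_equations(self):
        rng = np.random.default_rng(2)
        x = np.array([0.0, 5.0, 10.0, 20.0, 40.0])
        y = 0.012 * x + 0.03 + rng.normal(0, 0.005, size=5)
        cal = act.fit_calibration(list(zip(x, y)))
        # closed-form least squares
        A = np.vstack([x, np.ones_like(x)]).T
        slope, intercept = np.linalg.lstsq(A, y, rcond=None)[0]
        assert cal.slope == pytest.approx(slope, abs=1e-9)
        assert cal.intercept == pytest.approx(intercept, abs=1e-9)

    def test_duplicated_point_leaves_exact_fit_unchanged(self):
        standards = [(x, 0.01 * x) for x in (0.0, 10.0, 20.0)]
        cal1 = act.fit_calibration(standards)
        cal2 = act.fit_calibration(standards + [(10.0, 0.1)])
        assert cal2.slope == pytest.approx(cal1.slope, rel=1e-12)

    def test_identical_concentrations_rejected(self):
        with pytest.raises(ValueError):
            act.fit_calibration([(5.0, 0.1), (5.0, 0.2)])


class TestLinearRange:
    def test_perfect_line_takes_full_window(self):
        s = make_series(np.arange(1, 7) * 60.0, np.arange(1, 7) * 0.02)
        assert act.find_linear_range(s) == (0, 5)

    def test_plateau_truncates_window(self):
        t = np.arange(1, 9) * 60.0
        a = np.minimum(np.arange(1, 9), 5) * 0.05  # linear for 5 points, then flat
        window = act.find_linear_range(make_series(t, a))
        assert window == (0, 4)

    def test_too_few_points_signals_insufficient_data(self):
        s = make_series([0.0, 60.0, 120.0], [0.0, 0.1, 0.2])
        with pytest.raises(act.InsufficientDataError):
            act.find_linear_range(s)

    def test_agrees_with_exhaustive_window_search(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(4, 21))
            t = np.cumsum(rng.uniform(10, 60, size=n))
            a = 0.001 * t + rng.normal(0, rng.uniform(0, 0.05), size=n)
            s = make_series(t, a)
            got = act.find_linear_range(s, min_points=4, r2_threshold=0.99)
            best = None
            for length in range(n, 3, -1):  # longest first, earliest start wins
                for start in range(0, n - length + 1):
                    stop = start + length - 1
                    if act._r_squared(t[start : stop + 1], a[start : stop + 1]) >= 0.99:
                        best = (start, stop)
                        break
                if best:
                    break
            assert got == best


class TestSpecificActivity:
    def test_flat_series_is_below_detection(self):
        cal = act.fit_calibration([(0.0, 0.0), (100.0, 0.1)])
        res = act.specific_activity(make_series([60, 120, 180, 240], [0.2] * 4), cal)
        assert res.activity_nkat_per_mg == 0.0
        assert res.below_detection

    def test_unit_arithmetic(self):
        # 0.01 absorbance per 60 s, 0.001 abs/nmol, 0.001 mg enzyme
        t = np.arange(1, 6) * 60.0
        a = 0.01 / 60.0 * t
        cal = act.CalibrationCurve(slope=0.001, intercept=0.0, r2=1.0)
        res = act.specific_activity(make_series(t, a, mass=0.001), cal)
        assert res.activity_nkat_per_mg == pytest.approx(1000.0 / 6.0, rel=1e-9)

    def test_doubling_mass_halves_activity(self):
        t = np.arange(1, 6) * 60.0
        a = 0.0005 * t
        cal = act.CalibrationCurve(slope=0.001, intercept=0.0, r2=1.0)
        r1 = act.specific_activity(make_series(t, a, mass=0.001), cal)
        r2 = act.specific_activity(make_series(t, a, mass=0.002), cal)
        assert r1.activity_nkat_per_mg == pytest.approx(2 * r2.activity_nkat_per_mg)

    def test_invariant_under_time_shift_and_absorbance_offset(self):
        rng = np.random.default_rng(8)
        t = np.arange(1, 9) * 30.0
        a = 0.0004 * t + rng.normal(0, 1e-4, size=8)
        cal = act.CalibrationCurve(slope=0.002, intercept=0.0, r2=1.0)
        base = act.specific_activity(make_series(t, a), cal, r2_threshold=0.9)
        shifted = act.specific_activity(make_series(t + 500.0, a + 0.3), cal, r2_threshold=0.9)
        assert shifted.activity_nkat_per_mg == pytest.approx(
            base.activity_nkat_per_mg, rel=1e-9
        )

    def test_control_slope_subtracted(self):
        t = np.arange(1, 6) * 60.0
        cal = act.CalibrationCurve(slope=0.001, intercept=0.0, r2=1.0)
        sample = make_series(t, 0.001 * t)
        control = make_series(t, 0.0004 * t)
        res = act.specific_activity(sample, cal, control=control)
        expected = (0.001 - 0.0004) / 0.001 / 0.001
        assert res.activity_nkat_per_mg == pytest.approx(expected, rel=1e-9)

    def test_no_linear_window_propagates_signal(self):
        rng = np.random.default_rng(1)
        t = np.arange(1, 7) * 60.0
        a = rng.uniform(0, 1, size=6)  # pure noise, no linear stretch
        cal = act.CalibrationCurve(slope=0.001, intercept=0.0, r2=1.0)
        with pytest.raises(act.InsufficientDataError):
            act.specific_activity(make_series(t, a), cal, r2_threshold=0.9999)


class TestReplicateSummary:
    def test_constant_replicates(self):
        assert act.summarize_replicates([5.0, 5.0, 5.0]) == (5.0, 5.0, 5.0, 0.0)

    def test_inclusive_quartiles_by_hand(self):
        q1, med, q3, sd = act.summarize_replicates([1.0, 2.0, 3.0, 4.0])
        assert (q1, med, q3) == (1.75, 2.5, 3.25)
        assert sd == pytest.approx(np.std([1, 2, 3, 4], ddof=1))

    def test_single_value_has_no_sd(self):
        q1, med, q3, sd = act.summarize_replicates([7.0])
        assert q1 == med == q3 == 7.0
        assert sd is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            act.summarize_replicates([])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(values=st.lists(st.floats(-100, 400), min_size=1, max_size=9))
    def test_permutation_invariance(self, values):
        base = act.summarize_replicates(values)
        rev = act.summarize_replicates(list(reversed(values)))
        for x, y in zip(base, rev):
            if x is None:
                assert y is None
            else:
                assert x == pytest.approx(y, abs=1e-9)


class TestParameterRecovery:
    def test_noiseless_kinetics_recover_truth_exactly(self):
        sc = synthetic.KineticsScenario(noise_sd=0.0, seed=0)
        series, standards, truth = synthetic.make_kinetics(sc)
        cal = act.fit_calibration(standards)
        res = act.specific_activity(series, cal)
        assert res.activity_nkat_per_mg == pytest.approx(truth["activity"], rel=1e-6)

    def test_plateau_series_window_ends_at_onset(self):
        sc = synthetic.KineticsScenario(noise_sd=0.0, n_points=10, plateau_onset=6, seed=0)
        series, standards, _ = synthetic.make_kinetics(sc)
        window = act.find_linear_range(series)
        assert window[1] <= 6

    def test_noisy_median_recovery_within_three_se(self):
        estimates = []
        for seed in range(100):
            sc = synthetic.KineticsScenario(noise_sd=0.01, seed=seed)
            series, standards, truth = synthetic.make_kinetics(sc)
            cal = act.fit_calibration(standards)
            res = act.specific_activity(series, cal, r2_threshold=0.95)
            estimates.append(res.activity_nkat_per_mg)
        estimates = np.asarray(estimates)
        med = np.median(estimates)
        se_median = 1.2533 * estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(med - truth["activity"]) <= 3 * se_median
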