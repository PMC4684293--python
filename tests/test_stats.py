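"""RMR normalization, group summaries, Response Time, HSD, and GLM beta."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from wiggleindex import (
    BaselineZeroError,
    DecaySpec,
    GroupSummary,
    TimeCourse,
    compare_beta,
    compute_rmr,
    endpoint_rmr,
    fit_glm,
    response_time,
    simulate_timecourse,
    summarize_group,
    timecourses_from_table,
)

GRID = np.array([0.0, 5, 10, 15, 30, 45, 60, 120, 240])


def course(values, times=None, well="w1", group="g"):
    times = GRID if times is None else np.asarray(times, float)
    return TimeCourse(well_id=well, group=group, times=times, wi_values=np.asarray(values, float))


class TestComputeRMR:
    def test_worked_example(self):
        tc = course([10.0, 3.0], times=[0.0, 30.0])
        s = compute_rmr(tc)
        assert s.rmr[1] == 0.3
        assert s.baseline_wi == 10.0

    def test_baseline_point_is_one(self):
        s = compute_rmr(course(np.linspace(8, 2, 9)))
        assert s.rmr[0] == 1.0

    def test_constant_series_stays_at_one(self):
        s = compute_rmr(course([4.2] * 9))
        np.testing.assert_array_equal(s.rmr, 1.0)

    def test_zero_baseline_raises(self):
        with pytest.raises(BaselineZeroError):
            compute_rmr(course([0.0, 1.0], times=[0.0, 5.0]))

    def test_missing_baseline_sample_raises(self):
        with pytest.raises(ValueError, match="t = 0"):
            compute_rmr(course([1.0, 2.0], times=[5.0, 10.0]))

    @pytest.mark.parametrize("k", [0.5, 2.0, 8.0])
    def test_ratio_invariance_under_rescaling(self, k):
        """RMR only sees relative motility: scaling a well's WI cancels."""
        wi = np.array([10.0, 8.0, 5.0, 2.0])
        t = [0.0, 5.0, 10.0, 15.0]
        s1 = compute_rmr(course(wi, times=t))
        s2 = compute_rmr(course(k * wi, times=t))
        np.testing.assert_array_equal(s1.rmr, s2.rmr)


class TestSummarizeGroup:
    def make_series(self, rmr_by_well, times=(0.0, 240.0)):
        out = []
        for i, vals in enumerate(rmr_by_well):
            tc = course(np.asarray(vals) * 10.0, times=times, well=f"w{i}")
            out.append(compute_rmr(tc))
        return out

    def test_mean_of_two_wells(self):
        series = self.make_series([[1.0, 0.2], [1.0, 0.4]])
        sm = summarize_group(series)
        assert sm.mean[1] == pytest.approx(0.3)
        assert sm.n[1] == 2

    def test_identical_wells_zero_halfwidth(self):
        series = self.make_series([[1.0, 0.5]] * 4)
        sm = summarize_group(series)
        assert sm.ci_half[1] == pytest.approx(0.0, abs=1e-12)

    def test_halfwidth_matches_closed_form(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0.5, 0.1, 5)
        series = self.make_series([[1.0, v] for v in vals])
        sm = summarize_group(series)
        expected = sps.t.ppf(0.975, 4) * vals.std(ddof=1) / math.sqrt(5)
        assert sm.ci_half[1] == pytest.approx(expected, rel=1e-12)

    def test_single_well_has_no_interval(self):
        sm = summarize_group(self.make_series([[1.0, 0.5]]))
        assert math.isnan(sm.ci_half[1])
        assert sm.mean[1] == pytest.approx(0.5)

    def test_mixed_groups_rejected(self):
        a = compute_rmr(course([10, 5], times=[0, 5], group="a"))
        b = compute_rmr(course([10, 5], times=[0, 5], group="b"))
        with pytest.raises(ValueError, match="mixed groups"):
            summarize_group([a, b])


def summary_from(times, mean, half, group="g"):
    times = np.asarray(times, float)
    return GroupSummary(
        group=group,
        times=times,
        n=np.full(times.size, 5),
        mean=np.asarray(mean, float),
        ci_half=np.asarray(half, float),
    )


class TestResponseTime:
    def test_detection_from_second_sample(self):
        sm = summary_from(
            [0, 5, 10, 15], [1.0, 0.99, 0.6, 0.5], [0.05, 0.05, 0.05, 0.05]
        )
        assert response_time(sm).minutes == 10.0

    def test_irreversibility_clause(self):
        # dips at 15, recovers at 30, drops for good from 45
        sm = summary_from(
            [0, 15, 30, 45, 60],
            [1.0, 0.7, 0.98, 0.6, 0.55],
            [0.05, 0.05, 0.05, 0.05, 0.05],
        )
        assert response_time(sm).minutes == 45.0

    def test_censoring_when_never_significant(self):
        sm = summary_from([0, 120, 240], [1.0, 0.99, 1.01], [0.05, 0.05, 0.05])
        rt = response_time(sm)
        assert rt.censored and rt.minutes is None and rt.label == ">240"

    def test_missing_interval_never_qualifies(self):
        sm = summary_from([0, 240], [1.0, 0.2], [np.nan, np.nan])
        assert response_time(sm).censored

    def test_weaker_response_detected_no_earlier(self):
        """Raising every group mean can only delay (or keep) the detection."""
        times = [0, 5, 10, 15, 30]
        mean = np.array([1.0, 0.8, 0.7, 0.75, 0.6])
        half = np.full(5, 0.05)
        t1 = response_time(summary_from(times, mean, half)).minutes
        t2 = response_time(summary_from(times, mean + 0.15, half))
        assert t2.censored or t2.minutes >= t1


class TestEndpointRMR:
    def rmr_groups(self, means, seed, n=10, sd=0.05):
        rng = np.random.default_rng(seed)
        groups = {}
        for gi, m in enumerate(means):
            name = f"g{gi}"
            series = []
            for w in range(n):
                endpoint = rng.normal(m, sd)
                tc = course([10.0, 10.0 * endpoint], times=[0.0, 240.0],
                            well=f"{name}-w{w}", group=name)
                series.append(compute_rmr(tc))
            groups[name] = series
        return groups

    def test_gross_effect_is_significant(self):
        df, comps = endpoint_rmr(self.rmr_groups([0.2, 0.8], seed=0))
        assert len(comps) == 1
        assert comps[0].significant

    def test_null_rarely_significant(self):
        """Tukey HSD keeps its family error rate on equal-mean groups."""
        hits = sum(
            any(c.significant for c in endpoint_rmr(self.rmr_groups([0.5, 0.5], seed=s))[1])
            for s in range(40)
        )
        assert hits <= 4  # ~5% family rate; allow 10%

    def test_three_identical_groups_all_ns(self):
        _, comps = endpoint_rmr(self.rmr_groups([0.5, 0.5, 0.5], seed=3))
        assert len(comps) == 3
        assert all(not c.significant for c in comps)

    def test_well_missing_endpoint_excluded(self):
        groups = self.rmr_groups([0.5], seed=1, n=3)
        short = compute_rmr(course([10.0, 5.0], times=[0.0, 120.0],
                                   well="short", group="g0"))
        groups["g0"].append(short)
        df, _ = endpoint_rmr(groups)
        assert "short" not in set(df["well_id"])
        assert len(df) == 3

    def test_single_group_yields_no_comparisons(self):
        df, comps = endpoint_rmr(self.rmr_groups([0.4], seed=2))
        assert comps == [] and len(df) == 10


class TestFitGLM:
    def test_noiseless_line_recovered(self):
        tc = course(50.0 - 0.1 * GRID)
        fit = fit_glm(tc, transform="identity")
        assert fit.slope == pytest.approx(-0.1, abs=1e-12)
        assert fit.beta == pytest.approx(0.1, abs=1e-12)
        assert fit.adjusted_r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_zero_slope(self):
        fit = fit_glm(course([5.0] * 9), transform="identity")
        assert fit.slope == 0.0 and fit.beta == 0.0

    def test_log_shaped_decay_selects_log_transform(self):
        tc = course(40.0 - 12.0 * np.log10(GRID + 1.0))
        fit = fit_glm(tc, transform="auto")
        assert fit.transform == "log10p1"
        assert fit.adjusted_r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.slope == pytest.approx(-12.0, abs=1e-9)

    def test_reciprocal_convention(self):
        fit = fit_glm(course(50.0 - 0.1 * GRID), transform="identity",
                      beta_convention="reciprocal")
        assert fit.beta == pytest.approx(-10.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_glm(course([1.0, 2.0], times=[0.0, 5.0]))

    def test_beta_scales_with_wi_rescaling(self):
        tc = course(50.0 - 0.1 * GRID)
        k = 4.0
        tck = course(k * (50.0 - 0.1 * GRID))
        assert fit_glm(tck, "identity").beta == pytest.approx(
            k * fit_glm(tc, "identity").beta
        )

    def test_slope_recovery_under_noise(self):
        """Median recovered slope over many seeds is within 5% of truth."""
        slopes = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            wi = 50.0 - 0.1 * GRID + rng.normal(0, 1.0, GRID.size)
            slopes.append(fit_glm(course(wi), transform="identity").slope)
        assert np.median(slopes) == pytest.approx(-0.1, rel=0.05)


class TestCompareBeta:
    def fits(self, betas, group):
        return [
            type("F", (), {"beta": b, "group": group, "well_id": f"{group}-{i}"})()
            for i, b in enumerate(betas)
        ]

    def test_control_vs_itself_t0_p1(self):
        ctrl = self.fits([1.0, 1.2, 0.9, 1.1], "ctrl")
        summary, comps = compare_beta(
            {"ctrl": ctrl, "same": ctrl}, control_group="ctrl"
        )
        (c,) = comps
        assert c.statistic == pytest.approx(0.0, abs=1e-12)
        assert c.p_value == pytest.approx(1.0)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(0)
        ctrl = rng.normal(1.0, 0.1, 10)
        shifted = ctrl + 5 * 0.1 * np.sqrt(2)
        _, comps = compare_beta(
            {"ctrl": self.fits(ctrl, "ctrl"), "hit": self.fits(shifted, "hit")},
            control_group="ctrl",
        )
        assert comps[0].significant

    def test_null_type_one_control(self):
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            a = rng.normal(1.0, 0.1, 8)
            b = rng.normal(1.0, 0.1, 8)
            _, comps = compare_beta(
                {"ctrl": self.fits(a, "ctrl"), "g": self.fits(b, "g")},
                control_group="ctrl",
            )
            hits += bool(comps[0].significant)
        assert hits <= 8  # nominal 5% level, allow slack

    def test_degenerate_variance_unavailable(self):
        _, comps = compare_beta(
            {"ctrl": self.fits([1.0] * 4, "ctrl"), "g": self.fits([2.0] * 4, "g")},
            control_group="ctrl",
        )
        assert comps[0].statistic is None and comps[0].p_value is None

    def test_matched_constant_groups_p1(self):
        _, comps = compare_beta(
            {"ctrl": self.fits([1.0] * 4, "ctrl"), "g": self.fits([1.0] * 4, "g")},
            control_group="ctrl",
        )
        assert comps[0].p_value == 1.0


class TestTableRoundtrip:
    def test_grouping_and_exclusion(self, caplog):
        rows = []
        for wid, t0 in (("w1", True), ("w2", False)):
            times = GRID if t0 else GRID[1:]
            for t in times:
                rows.append(
                    dict(well_id=wid, genotype="A", insecticide="imi",
                         dose_ppm=48.0, time_min=t, wi_value=5.0,
                         pixels_above_threshold=1)
                )
        df = pd.DataFrame(rows)
        courses = timecourses_from_table(df)
        assert [c.well_id for c in courses] == ["w1"]
        assert courses[0].group == "A|imi|48ppm"
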