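"""Trend line, axis crossing, eradication likelihood, and the summary table."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ineqtrend.trend import (
    TrendLine,
    axis_intersection,
    eradication_likelihood,
    fit_trend,
    summarize,
)


def ols_closed_form(p1, p0):
    x, y = np.asarray(p1), np.asarray(p0)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    return slope, y.mean() - slope * x.mean()


def constant_draws(points, n_sim=1000):
    """Draw array where every simulation repeats the same wave points."""
    return np.tile(np.asarray(points, dtype=float)[None, :, :], (n_sim, 1, 1))


class TestFitTrend:
    def test_identity_line(self):
        line = fit_trend([(0.1, 0.1), (0.2, 0.2), (0.3, 0.3)])
        assert line.slope == pytest.approx(1.0)
        assert line.intercept == pytest.approx(0.0, abs=1e-15)

    def test_matches_normal_equations(self):
        pts = [(0.10, 0.15), (0.20, 0.22), (0.25, 0.24), (0.30, 0.31)]
        line = fit_trend(pts)
        slope, intercept = ols_closed_form(*zip(*pts))
        assert line.slope == pytest.approx(slope, abs=1e-12)
        assert line.intercept == pytest.approx(intercept, abs=1e-12)

    def test_two_points_interpolated(self):
        line = fit_trend([(0.1, 0.3), (0.4, 0.15)])
        for x, y in [(0.1, 0.3), (0.4, 0.15)]:
            assert line.intercept + line.slope * x == pytest.approx(y, abs=1e-12)

    @given(st.floats(-0.2, 0.2))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_shift_in_p0_moves_only_intercept(self, c):
        pts = np.array([(0.10, 0.15), (0.20, 0.22), (0.25, 0.24), (0.30, 0.31)])
        base = fit_trend(pts)
        shifted = fit_trend(pts + [0.0, c])
        assert shifted.slope == pytest.approx(base.slope, abs=1e-10)
        assert shifted.intercept == pytest.approx(base.intercept + c, abs=1e-10)

    def test_scaling_prevalences_scales_intercept_only(self):
        pts = np.array([(0.10, 0.15), (0.20, 0.22), (0.30, 0.31)])
        base = fit_trend(pts)
        scaled = fit_trend(0.5 * pts)
        assert scaled.slope == pytest.approx(base.slope, abs=1e-12)
        assert scaled.intercept == pytest.approx(0.5 * base.intercept, abs=1e-12)

    def test_vertical_line_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_trend([(0.2, 0.1), (0.2, 0.3)])


class TestAxisIntersection:
    @pytest.mark.parametrize(
        "slope, intercept, exp",
        [
            (0.72, 0.094, (0.0, 0.094, "y-axis")),
            (1.0, -0.02, (0.02, 0.0, "x-axis")),
            (1.0, 0.0, (0.0, 0.0, "y-axis")),
            (-0.5, -0.01, (None, None, "none")),
        ],
    )
    def test_first_crossing(self, slope, intercept, exp):
        x, y, axis = axis_intersection(TrendLine(slope, intercept, 4))
        assert axis == exp[2]
        if exp[0] is not None:
            assert x == pytest.approx(exp[0], abs=1e-12)
            assert y == pytest.approx(exp[1], abs=1e-12)
        else:
            assert np.isnan(x) and np.isnan(y)


class TestEradicationLikelihood:
    def test_noise_free_intercept_above_threshold_gives_zero(self):
        pts = [(0.22, 0.094 + 0.72 * 0.22), (0.17, 0.094 + 0.72 * 0.17),
               (0.10, 0.094 + 0.72 * 0.10)]
        res = eradication_likelihood(constant_draws(pts))
        assert res.eradication_likelihood == 0.0
        assert res.line.intercept == pytest.approx(0.094, abs=1e-12)

    def test_noise_free_intercept_inside_zone_gives_one(self):
        pts = [(p1, 0.02 + 1.0 * p1) for p1 in (0.25, 0.15, 0.08)]
        res = eradication_likelihood(constant_draws(pts))
        assert res.eradication_likelihood == 1.0

    def test_fifty_fifty_mixture_gives_half(self):
        a = constant_draws([(p1, 0.02 + p1) for p1 in (0.25, 0.15, 0.08)], 500)
        b = constant_draws([(p1, 0.10 + p1) for p1 in (0.25, 0.15, 0.08)], 500)
        res = eradication_likelihood(np.concatenate([a, b]))
        assert res.eradication_likelihood == 0.5

    def test_x_axis_crossing_counts(self):
        # intercept -0.02, slope 1: crossing at (0.02, 0) inside the zone
        pts = [(p1, -0.02 + p1) for p1 in (0.25, 0.15, 0.08)]
        res = eradication_likelihood(constant_draws(pts))
        assert res.eradication_likelihood == 1.0
        # crossing at (0.08, 0) outside
        pts = [(p1, -0.08 + p1) for p1 in (0.25, 0.15, 0.12)]
        assert eradication_likelihood(constant_draws(pts)).eradication_likelihood == 0.0

    def test_negative_slope_missing_axes_not_eradicating(self):
        pts = [(p1, -0.01 - 0.5 * p1 + 0.6) for p1 in (0.9, 0.8, 0.7)]
        # slope -0.5, intercept 0.59 -> y-axis at 0.59, not eradicating
        res = eradication_likelihood(constant_draws(pts))
        assert res.eradication_likelihood == 0.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        base = np.array([(0.22, 0.20), (0.17, 0.18), (0.10, 0.12)])
        sim = base[None] + rng.normal(0, 0.04, size=(2000, 3, 2))
        prev = -1.0
        for thr in (0.01, 0.03, 0.05, 0.10, 0.25):
            lik = eradication_likelihood(sim, threshold=thr).eradication_likelihood
            assert lik >= prev
            prev = lik

    def test_intercept_ci_is_percentile_of_sim_intercepts(self):
        rng = np.random.default_rng(1)
        sim = np.array([(0.2, 0.2), (0.1, 0.12)])[None] + rng.normal(0, 0.02, (3000, 2, 2))
        res = eradication_likelihood(sim)
        ic = res.per_sim_intercepts
        assert res.intercept_ci == pytest.approx(
            (np.percentile(ic, 2.5), np.percentile(ic, 97.5)), abs=1e-12
        )

    def test_too_many_degenerate_sims_abort(self):
        sim = constant_draws([(0.2, 0.2), (0.2, 0.3)], 100)  # identical p1 everywhere
        with pytest.raises(RuntimeError, match="identical p1"):
            eradication_likelihood(sim)

    def test_bad_threshold_rejected(self):
        sim = constant_draws([(0.2, 0.2), (0.1, 0.1)], 100)
        with pytest.raises(ValueError, match="threshold"):
            eradication_likelihood(sim, threshold=1.5)


class TestSummarize:
    def test_table_row_rendering(self):
        res = eradication_likelihood(
            constant_draws([(0.22, 0.094 + 0.72 * 0.22), (0.10, 0.094 + 0.72 * 0.10)]),
            stratum={"gender": "boy"},
        )
        # emulate a stratum whose likelihood is small but nonzero
        res.eradication_likelihood = 0.004
        res.intercept_ci = (0.061, 0.127)
        df = summarize([res])
        row = df.iloc[0]
        assert row["intercept_pct"] == 9.4
        assert (row["ci_low_pct"], row["ci_high_pct"]) == (6.1, 12.7)
        assert row["eradication_pct"] == "<1"

    def test_empty_input_gives_empty_table_with_header(self):
        df = summarize([])
        assert df.empty
        assert "intercept_pct" in df.columns

    def test_region_ordering(self):
        rows = []
        for region in ("West", "North"):
            r = eradication_likelihood(
                constant_draws([(0.2, 0.2), (0.1, 0.12)]),
                stratum={"region": region, "gender": "boy"},
            )
            rows.append(r)
        df = summarize(rows, region_order=("all", "North", "East", "South", "West"))
        assert list(df["region"]) == ["North", "West"]
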