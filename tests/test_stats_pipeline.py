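"""Group summaries, calibration thresholds and nonparametric tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from canalflow.stats_pipeline import (
    PolynomialFit,
    compare_models,
    fit_flow_pressure_curve,
    maxima_table,
    model_reduction_table,
    prevalence_stats,
    summarize_groups,
    threshold_flow_rate,
    within_model_ranks,
)
from canalflow.synthetic_data import (
    ExperimentDesign,
    GroupGeneratorSpec,
    generate_experiment,
)


def _maxima_frame(values_by_group):
    rows = []
    for (model, depth, flow), values in values_by_group.items():
        for rep, v in enumerate(values):
            rows.append(
                {
                    "model": model,
                    "depth_mm": depth,
                    "flow_mL_min": flow,
                    "replicate": rep,
                    "max_kPa": v,
                }
            )
    return pd.DataFrame(rows)


class TestSummarizeGroups:
    def test_median_of_three(self):
        df = _maxima_frame({("separate", 1.0, 1.5): [1.0, 2.0, 3.0]})
        out = summarize_groups(df)
        assert out.loc[0, "median_kPa"] == 2.0
        assert out.loc[0, "n"] == 3

    def test_noiseless_replicates_zero_iqr(self):
        df = _maxima_frame({("separate", 1.0, 15.6): [79.49] * 12})
        out = summarize_groups(df)
        assert out.loc[0, "median_kPa"] == pytest.approx(79.49)
        assert out.loc[0, "iqr_kPa"] == 0.0

    def test_permutation_invariance(self):
        values = [3.1, 1.2, 9.9, 4.4, 2.0]
        a = summarize_groups(_maxima_frame({("separate", 1.0, 1.5): values}))
        b = summarize_groups(_maxima_frame({("separate", 1.0, 1.5): values[::-1]}))
        assert a.loc[0, "median_kPa"] == b.loc[0, "median_kPa"]
        assert a.loc[0, "iqr_kPa"] == b.loc[0, "iqr_kPa"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_groups(pd.DataFrame(columns=["model", "max_kPa"]))


class TestReductionTable:
    def test_published_medians_give_ninety_percent_reduction(self):
        df = _maxima_frame(
            {
                ("separate", 1.0, 15.6): [79.49] * 3,
                ("anastomosis", 1.0, 15.6): [7.85] * 3,
            }
        )
        red = model_reduction_table(summarize_groups(df))
        assert red.loc[0, "reduction_pct"] == pytest.approx(90.12, abs=0.01)

    def test_missing_model_rejected(self):
        df = _maxima_frame({("separate", 1.0, 15.6): [79.49] * 3})
        with pytest.raises(ValueError, match="anastomosis"):
            model_reduction_table(summarize_groups(df))


class TestPolynomialFit:
    def test_exact_recovery_of_noiseless_quadratic(self):
        q = np.arange(1.0, 17.0)
        p = 0.1 + 0.2 * q + 0.3 * q * q
        fit = fit_flow_pressure_curve(np.column_stack([q, p]))
        assert fit.a == pytest.approx(0.1, abs=1e-9)
        assert fit.b == pytest.approx(0.2, abs=1e-9)
        assert fit.c == pytest.approx(0.3, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_pressure_gives_zero_slope_terms(self):
        q = np.arange(1.0, 9.0)
        fit = fit_flow_pressure_curve(np.column_stack([q, np.full_like(q, 2.5)]))
        assert fit.b == pytest.approx(0.0, abs=1e-10)
        assert fit.c == pytest.approx(0.0, abs=1e-10)

    def test_coefficients_unbiased_under_noise(self):
        """Monte-Carlo oracle: mean coefficient bias < 0.01 over 500 seeds."""
        q = np.arange(1.0, 17.0)
        truth = np.array([0.1, 0.2, 0.3])
        coefs = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            p = truth[0] + truth[1] * q + truth[2] * q * q + rng.normal(0, 0.2, q.size)
            fit = fit_flow_pressure_curve(np.column_stack([q, p]))
            coefs.append([fit.a, fit.b, fit.c])
        bias = np.abs(np.mean(coefs, axis=0) - truth)
        assert np.all(bias < 0.01)

    def test_fewer_than_three_distinct_flows_rejected(self):
        with pytest.raises(ValueError):
            fit_flow_pressure_curve([(1.0, 1.0), (1.0, 2.0), (2.0, 3.0)])


class TestThresholdFlowRate:
    def test_pure_quadratic_closed_form(self):
        fit = PolynomialFit(a=0, b=0, c=1, r_squared=1, residual_scale=0,
                            q_min=0.5, q_max=16.0)
        assert threshold_flow_rate(fit, 4.0) == pytest.approx(2.0)

    def test_curve_never_reaching_threshold(self):
        fit = PolynomialFit(a=0.5, b=0.1, c=0.0, r_squared=1, residual_scale=0,
                            q_min=1.0, q_max=16.0)
        assert threshold_flow_rate(fit, 4.0) is None

    def test_published_low_flow_medians_bound_threshold(self):
        # separate model, 1 mm: the 4 kPa crossing falls in (1.5, 2.5]
        fit = fit_flow_pressure_curve([(1.5, 2.59), (2.5, 4.58), (9.5, 8.63)])
        root = threshold_flow_rate(fit, 4.0)
        assert root is not None
        assert 1.5 < root <= 2.5
        assert threshold_flow_rate(fit, 4.0, grid=0.5) == pytest.approx(2.5)

    def test_uniform_pressure_increase_lowers_threshold(self):
        base = fit_flow_pressure_curve([(1.5, 2.59), (2.5, 4.58), (9.5, 8.63)])
        shifted = fit_flow_pressure_curve([(1.5, 3.59), (2.5, 5.58), (9.5, 9.63)])
        assert threshold_flow_rate(shifted, 4.0) < threshold_flow_rate(base, 4.0)


def _brute_force_mw_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating every group split."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)

    def ustat(x, y):
        x = np.asarray(x)[:, None]
        y = np.asarray(y)[None, :]
        return float(np.sum(x > y) + 0.5 * np.sum(x == y))

    u_obs = ustat(a, b)
    us = []
    for comb in itertools.combinations(range(n + m), n):
        mask = np.zeros(n + m, bool)
        mask[list(comb)] = True
        us.append(ustat(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    u_big = max(u_obs, n * m - u_obs)
    return min(1.0, 2.0 * np.mean(us >= u_big))


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        res = compare_models([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_minimum_p(self):
        from math import comb

        a = np.arange(12.0)
        b = np.arange(100.0, 112.0)
        res = compare_models(a, b)
        assert res.u_statistic == 0.0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / comb(24, 12))

    def test_u_complement_identity(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=8), rng.normal(size=6)
        res_ab = compare_models(a, b)
        res_ba = compare_models(b, a)
        assert res_ab.u_statistic + res_ba.u_statistic == pytest.approx(48.0)

    def test_agrees_with_brute_force_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(8):
            a = rng.normal(size=int(rng.integers(3, 7)))
            b = rng.normal(size=int(rng.integers(3, 7))) + rng.normal()
            res = compare_models(a, b)
            assert res.p_value == pytest.approx(_brute_force_mw_p(a, b), abs=1e-12)

    def test_all_tied_input_flagged(self):
        res = compare_models([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.degenerate
        assert res.p_value == 1.0

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_models([1.0], [2.0, 3.0])


class TestWithinModelRanks:
    def _frame(self, group_values, reps=12):
        rows = []
        for (depth, flow), base in group_values.items():
            for rep in range(reps):
                rows.append(
                    {
                        "model": "separate",
                        "depth_mm": depth,
                        "flow_mL_min": flow,
                        "replicate": rep,
                        "max_kPa": base + 0.001 * rep,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_groups_one_letter(self):
        conditions = {(d, q): 5.0 for d in (1.0, 3.0) for q in (1.5, 2.5, 9.5, 15.6)}
        res = within_model_ranks(self._frame(conditions))
        assert res.p_value > 0.05
        assert set(res.letters.values()) == {"A"}

    def test_large_shifts_order_mean_ranks(self):
        conditions = {
            (1.0, 1.5): 1.0, (1.0, 2.5): 10.0, (1.0, 9.5): 100.0, (1.0, 15.6): 1000.0,
            (3.0, 1.5): 0.5, (3.0, 2.5): 5.0, (3.0, 9.5): 50.0, (3.0, 15.6): 500.0,
        }
        res = within_model_ranks(self._frame(conditions))
        ordered = res.mean_ranks.sort_values(ascending=False).index.tolist()
        expected = [
            f"{d}/{q}"
            for (d, q) in sorted(conditions, key=conditions.get, reverse=True)
        ]
        assert ordered == expected
        assert res.p_value < 0.001

    def test_extreme_groups_get_distinct_letters(self):
        conditions = {
            (1.0, 1.5): 1.0, (1.0, 2.5): 1.0, (1.0, 9.5): 1.0, (1.0, 15.6): 1000.0,
            (3.0, 1.5): 1.0, (3.0, 2.5): 1.0, (3.0, 9.5): 1.0, (3.0, 15.6): 1000.0,
        }
        res = within_model_ranks(self._frame(conditions))
        top = res.mean_ranks.idxmax()
        bottom = res.mean_ranks.idxmin()
        assert set(res.letters[top]) != set(res.letters[bottom])

    def test_unbalanced_blocks_rejected(self):
        frame = self._frame({(1.0, 1.5): 1.0, (1.0, 2.5): 2.0, (1.0, 9.5): 3.0})
        frame = frame.drop(index=frame.index[0])
        with pytest.raises(ValueError, match="unbalanced"):
            within_model_ranks(frame)


class TestPrevalence:
    def test_published_survey_percentages(self):
        counts = pd.DataFrame(
            [
                {"stratum": "first", "numerator": 17, "denominator": 34},
                {"stratum": "second", "numerator": 17, "denominator": 50},
                {"stratum": "pooled", "numerator": 34, "denominator": 84},
            ]
        )
        out = prevalence_stats(counts).set_index("stratum")
        assert out.loc["first", "percent"] == 50.00
        assert out.loc["second", "percent"] == 34.00
        assert out.loc["pooled", "percent"] == 40.48

    def test_zero_denominator_rejected(self):
        counts = pd.DataFrame([{"stratum": "x", "numerator": 0, "denominator": 0}])
        with pytest.raises(ValueError):
            prevalence_stats(counts)

    def test_numerator_exceeding_denominator_rejected(self):
        counts = pd.DataFrame([{"stratum": "x", "numerator": 5, "denominator": 4}])
        with pytest.raises(ValueError):
            prevalence_stats(counts)


class TestPipelineRoundTrip:
    def test_noiseless_generator_reproduces_every_configured_median(self):
        from canalflow.synthetic_data import BENCH_GROUP_STATS

        specs = {
            key: GroupGeneratorSpec(target_median=med, dispersion=0.0, noise_sd=0.0)
            for key, (med, iqr) in BENCH_GROUP_STATS.items()
        }
        design = ExperimentDesign(seed=0)
        recordings, truth = generate_experiment(design, specs)
        summary = summarize_groups(maxima_table(recordings))
        merged = summary.merge(truth, on=["model", "depth_mm", "flow_mL_min"])
        assert len(merged) == 16
        np.testing.assert_allclose(
            merged["median_kPa"], merged["true_median_kPa"], rtol=0, atol=1e-12
        )
        np.testing.assert_allclose(merged["iqr_kPa"], 0.0, atol=1e-12)
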