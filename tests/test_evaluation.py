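"""Interpolators, holdout harness, imputation study, prediction, summaries."""

import numpy as np
import pytest

from mmgrowth import (MMParams, c1_birth_correlation, holdout_experiment,
                      imputation_experiment, interpolate_linear,
                      interpolate_locf, interpolate_loess, interpolate_spline,
                      make_mm_interpolator, mm_value, prediction_experiment,
                      summarize_rmse)
from mmgrowth.evaluation import select_holdouts

from conftest import VISIT_AGES, make_series


class TestLocf:
    def test_carries_last_prior_value(self):
        assert interpolate_locf([30, 365], [4.0, 9.0], 120) == 4.0

    def test_before_all_observations_errors(self):
        with pytest.raises(ValueError):
            interpolate_locf([30, 365], [4.0, 9.0], 10)

    def test_after_all_observations_takes_last(self):
        assert interpolate_locf([30, 365], [4.0, 9.0], 1000) == 9.0


class TestLinear:
    def test_exact_on_collinear(self):
        ages = np.array([1, 100, 300, 700], float)
        assert interpolate_linear(ages, 3 + 0.01 * ages, 450) == pytest.approx(7.5)

    def test_two_point_hand_ols(self):
        assert interpolate_linear([0, 100], [3.0, 5.0], 50) == pytest.approx(4.0)

    def test_order_invariant(self):
        ages = np.array([700, 1, 300, 100], float)
        vals = np.array([9.1, 3.2, 6.4, 4.4])
        assert interpolate_linear(ages, vals, 450) == pytest.approx(
            interpolate_linear(ages[::-1], vals[::-1], 450))

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            interpolate_linear([1], [3.0], 10)
        with pytest.raises(ValueError):
            interpolate_linear([5, 5], [3.0, 3.1], 10)


class TestSmoothers:
    @pytest.mark.parametrize("func", [interpolate_loess, interpolate_spline])
    def test_preserve_linear_data(self, func):
        ages = np.arange(0, 1100, 100, dtype=float)
        vals = 3 + 0.01 * ages
        assert func(ages, vals, 450.0) == pytest.approx(7.5, abs=1e-6)

    @pytest.mark.parametrize("func", [interpolate_loess, interpolate_spline])
    def test_small_series_falls_back_to_linear(self, func, caplog):
        ages = np.array([1.0, 200.0, 900.0])
        vals = 3 + 0.01 * ages
        with caplog.at_level("WARNING"):
            out = func(ages, vals, 450.0)
        assert out == pytest.approx(interpolate_linear(ages, vals, 450.0))
        assert any("fallback" in r.message for r in caplog.records)

    def test_smoother_beats_locf_on_curve(self):
        p = MMParams(15.0, 400.0, 3.3)
        ages = VISIT_AGES
        vals = mm_value(p, ages)
        hold = 4  # age 365, interior
        rest_a, rest_v = np.delete(ages, hold), np.delete(vals, hold)
        truth = vals[hold]
        locf_err = abs(interpolate_locf(rest_a, rest_v, ages[hold]) - truth)
        for func in (interpolate_loess, interpolate_spline):
            assert abs(func(rest_a, rest_v, ages[hold]) - truth) < locf_err


class TestHoldout:
    def test_selection_depends_only_on_cohort_and_seed(self, small_cohort):
        cohort, _, _ = small_cohort
        assert select_holdouts(cohort, 77) == select_holdouts(cohort, 77)
        assert select_holdouts(cohort, 77) != select_holdouts(cohort, 78)

    def test_same_seed_identical_summaries(self, small_cohort):
        cohort, _, _ = small_cohort
        sub = cohort[:40]
        s1, d1 = holdout_experiment(sub, ["locf", "linear"], seed=5)
        s2, d2 = holdout_experiment(sub, ["linear", "locf"], seed=5)
        assert s1["locf"] == s2["locf"] and s1["linear"] == s2["linear"]
        assert sorted(d1["holdout_age"]) == sorted(d2["holdout_age"])

    def test_mm_wins_on_noise_free_curve_data(self):
        rng = np.random.default_rng(12)
        cohort = [make_series(MMParams(rng.uniform(12, 18), rng.uniform(300, 600),
                                       rng.uniform(2.8, 4.0)), subject_id=f"S{i}")
                  for i in range(25)]
        summaries, _ = holdout_experiment(
            cohort, ["mm", "locf", "linear", "loess", "spline"], seed=1234)
        assert summaries["mm"].mean < 1e-6
        for name in ("locf", "linear", "loess", "spline"):
            assert summaries["mm"].mean <= summaries[name].mean

    def test_unknown_method_errors(self, small_cohort):
        cohort, _, _ = small_cohort
        with pytest.raises(ValueError, match="unknown interpolation method"):
            holdout_experiment(cohort[:5], ["sitar"], seed=1)

    def test_subject_conservation(self, small_cohort):
        cohort, _, _ = small_cohort
        sub = cohort[:60]
        summaries, _ = holdout_experiment(sub, ["mm", "locf"], seed=3)
        s = summaries["mm"]
        n_ineligible = len(sub) - len(select_holdouts(sub, 3))
        assert s.n_subjects + s.n_failures + n_ineligible == len(sub)


class TestImputation:
    def test_empty_dropset_is_exactly_zero(self, small_cohort):
        cohort, _, _ = small_cohort
        res = imputation_experiment(cohort[:30], subset=7, max_drop=1)
        assert res[0].dropped_visits == ()
        assert res[0].delta_rmse == 0.0

    def test_noise_free_cohort_identifiable_without_mid_visits(self):
        rng = np.random.default_rng(3)
        cohort = [make_series(MMParams(rng.uniform(12, 18), rng.uniform(300, 600),
                                       rng.uniform(2.8, 4.0)),
                              ages=np.array([1, 32, 68, 121, 191, 274, 354], float),
                              subject_id=f"S{i}")
                  for i in range(10)]
        res = imputation_experiment(cohort, subset=7, max_drop=3)
        for r in res:
            if r.degenerate or 1 in r.dropped_visits or len(r.dropped_visits) > 3:
                continue
            assert abs(r.delta_rmse) < 1e-6, r

    def test_visit1_costs_most_among_singles(self, small_cohort):
        cohort, _, _ = small_cohort
        res = imputation_experiment(cohort[:60], subset=7, max_drop=1)
        singles = {r.dropped_visits[0]: r.delta_rmse for r in res
                   if len(r.dropped_visits) == 1}
        assert singles[1] == max(singles.values())

    def test_degenerate_combinations_flagged(self, small_cohort):
        cohort, _, _ = small_cohort
        res = imputation_experiment(cohort[:5], subset=7, max_drop=5)
        degenerate = [r for r in res if r.degenerate]
        assert degenerate and all(len(r.dropped_visits) == 5 for r in degenerate)

    def test_subset_validation(self, small_cohort):
        with pytest.raises(ValueError):
            imputation_experiment(small_cohort[0][:2], subset=9)


class TestPrediction:
    def test_noise_free_year1_extrapolates_exactly(self):
        ages = np.array([1, 32, 68, 121, 191, 274, 354, 450, 550, 800, 900, 1100], float)
        cohort = [make_series(MMParams(15.0, 400.0, 3.3), ages=ages)]
        res, nf, ni = prediction_experiment(cohort, fit_window="Y1")
        assert nf == 0 and ni == 0
        assert res[0].eval_window == "Y2-3"
        assert res[0].rmse < 1e-8

    def test_mean_rmse_ordering_across_windows(self, small_cohort):
        cohort, _, _ = small_cohort
        means = {}
        for fw, ew in [("Y1-3", "Y1-3"), ("Y1+Y2", "Y3"), ("Y1", "Y2-3")]:
            res, _, _ = prediction_experiment(cohort, fit_window=fw)
            means[fw] = np.mean([r.rmse for r in res if r.eval_window == ew])
        assert means["Y1-3"] <= means["Y1+Y2"] <= means["Y1"]

    def test_ineligible_subjects_counted(self):
        sparse = [make_series(MMParams(15, 400, 3.3),
                              ages=np.array([1, 100, 200, 300, 360, 500], float))]
        res, nf, ni = prediction_experiment(sparse, fit_window="Y1+Y2")
        assert res == [] and ni == 1

    def test_invalid_window(self, small_cohort):
        with pytest.raises(ValueError):
            prediction_experiment(small_cohort[0][:1], fit_window="Y2")


class TestSummaries:
    def test_constant_list(self):
        s = summarize_rmse([0.3, 0.3, 0.3])
        assert s.mean == s.median == 0.3
        assert s.sd == 0.0 and s.iqr == 0.0

    def test_quantile_convention(self):
        s = summarize_rmse([1, 2, 3, 4])
        assert s.median == pytest.approx(2.5)
        assert s.iqr == pytest.approx(1.5)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(0.1, 1.0, 31)
        a, b = summarize_rmse(v), summarize_rmse(rng.permutation(v))
        for field in ("mean", "sd", "median", "iqr", "p90", "min", "max"):
            assert getattr(a, field) == pytest.approx(getattr(b, field), rel=1e-12)

    def test_invariants(self):
        rng = np.random.default_rng(9)
        s = summarize_rmse(rng.uniform(0, 2, 50))
        assert s.min <= s.median <= s.p90 <= s.max
        assert s.iqr >= 0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_rmse([])


class TestSpearman:
    def test_monotone_pairs(self):
        assert c1_birth_correlation([1, 2, 3, 4], [10, 20, 30, 40]) == 1.0
        assert c1_birth_correlation([1, 2, 3, 4], [40, 30, 20, 10]) == -1.0

    def test_validation(self):
        with pytest.raises(ValueError):
            c1_birth_correlation([1, 2], [1, 2])
        with pytest.raises(ValueError):
            c1_birth_correlation([1, 1, 1], [1, 2, 3])

    def test_recovers_birth_size_association(self, small_cohort):
        from mmgrowth import fit_mm
        cohort, truths, _ = small_cohort
        tmap = {t.subject_id: t for t in truths}
        c1s, births = [], []
        for s in cohort:
            res = fit_mm(s)
            if res.converged:
                c1s.append(res.params.c1)
                births.append(tmap[s.subject_id].params.c1)
        rho = c1_birth_correlation(c1s, births)
        assert rho > 0.7  # fitted intercept tracks true birth size
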