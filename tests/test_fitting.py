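"""Categorization, bounded fitting, goodness-of-fit, and model selection."""

import math

import numpy as np
import pytest
from scipy import stats

from obscpipe import fitting, models, simulate
from obscpipe.fitting import (DEFAULT_THRESHOLDS, FittedModel, aic, categorize,
                              combined_criterion, fit_model, from_params,
                              lack_of_fit, plausibility_check, select_model)
from tests.conftest import dataset_from_means, dataset_from_values


class TestCategorize:
    @pytest.mark.parametrize("means,expected", [
        # steadily decreasing, all steps large or short runs
        ({0: 1.0, 5: 0.9, 15: 0.7, 50: 0.4, 150: 0.2}, "Decreasing"),
        # one group mean at 115% triggers Growth
        ({0: 1.0, 5: 1.15, 15: 0.8, 50: 0.4, 150: 0.1}, "Growth"),
        # run of <15% steps flanked by >15% steps
        ({0: 1.0, 5: 0.70, 15: 0.65, 50: 0.62, 150: 0.60, 500: 0.20}, "Plateau"),
        # exactly at the 110% boundary counts as Growth
        ({0: 1.0, 5: 1.10, 15: 0.8, 50: 0.3}, "Growth"),
    ])
    def test_heuristic_rules(self, means, expected):
        ds = dataset_from_means({float(k): v for k, v in means.items()})
        assert categorize(ds) == expected

    def test_needs_four_dose_groups(self):
        ds = dataset_from_means({0.0: 1.0, 5.0: 0.5, 10.0: 0.2})
        with pytest.raises(ValueError):
            categorize(ds)

    def test_both_flank_requirement_is_configurable(self):
        # plateau at the end of the dose range: only a left flank exists
        means = {0.0: 1.0, 5.0: 0.6, 15.0: 0.55, 50.0: 0.52, 150.0: 0.50}
        ds = dataset_from_means(means)
        assert categorize(ds) == "Plateau"
        strict = fitting.HeuristicThresholds(require_both_flanks=True)
        assert categorize(ds, strict) == "Decreasing"


class TestFitModel:
    def test_noiseless_data_recovered_exactly(self, standard_doses):
        spec = simulate.SimCurveSpec("LL.4", {"b": 2.0, "c": 0.1, "e": 50.0},
                                     standard_doses, n_reps=3, noise_sd=0.0)
        fit = fit_model(models.get_spec("LL.4"),
                        simulate.generate_dose_response(spec))
        assert fit.converged
        assert fit.rss < 1e-10
        for name, true in (("b", 2.0), ("c", 0.1), ("e", 50.0)):
            assert abs(fit.estimates[name] - true) / true < 1e-3

    def test_noisy_midpoint_recovery(self, standard_doses):
        spec = simulate.SimCurveSpec("LL.4", {"b": 2.0, "c": 0.1, "e": 50.0},
                                     standard_doses, n_reps=4, noise_sd=0.05,
                                     seed=11)
        fit = fit_model(models.get_spec("LL.4"),
                        simulate.generate_dose_response(spec), seed=0)
        assert abs(fit.estimates["e"] - 50.0) / 50.0 < 0.25

    def test_identifiability_guard(self):
        ds = dataset_from_means({0.0: 1.0, 5.0: 1.2, 25.0: 0.6, 100.0: 0.1})
        with pytest.raises(ValueError):
            fit_model(models.get_spec("CRS.5a"), ds)  # 5 free params, 4 doses

    def test_estimates_respect_bounds(self, standard_doses):
        spec = simulate.SimCurveSpec("W1.4", {"b": 2.0, "c": 0.05, "e": 50.0},
                                     standard_doses, n_reps=4, noise_sd=0.1,
                                     seed=3)
        fit = fit_model(models.get_spec("W1.4"),
                        simulate.generate_dose_response(spec), seed=0)
        lo, hi = fit.spec.bounds_arrays()
        vals = np.array([fit.estimates[p] for p in fit.spec.free_params])
        assert np.all(vals >= lo) and np.all(vals <= hi)


class TestLackOfFit:
    def test_hand_computed_f_test(self):
        # 3 doses x 2 reps against a fixed exponential-decay curve
        data = {0.0: [1.02, 0.98], 10.0: [0.55, 0.65], 20.0: [0.30, 0.20]}
        ds = dataset_from_values(data)
        fit = from_params("EXD.3", c=0.1, e=12.0)
        pred = {d: 0.1 + 0.9 * math.exp(-d / 12.0) for d in data}
        rss_model = sum((v - pred[d]) ** 2 for d, vs in data.items() for v in vs)
        fit.rss = rss_model
        fit.n_obs = 6
        # saturated model: per-dose means
        rss_sat = sum((v - np.mean(vs)) ** 2 for vs in data.values() for v in vs)
        f_hand = ((rss_model - rss_sat) / (3 - 2)) / (rss_sat / (6 - 3))
        p_hand = stats.f.sf(f_hand, 1, 3)
        assert lack_of_fit(fit, ds) == pytest.approx(p_hand, abs=1e-10)

    def test_model_matching_cell_means_gives_p_one(self):
        # replicates symmetric about the curve: group means lie on the curve
        e = 10.0
        delta = 0.02
        data = {d: [math.exp(-d / e) - delta, math.exp(-d / e) + delta]
                for d in (0.0, 5.0, 20.0)}
        ds = dataset_from_values(data)
        fit = from_params("EXD.3", c=1e-9, e=e)
        fit.rss = sum((v - math.exp(-d / e)) ** 2
                      for d, vs in data.items() for v in vs)
        fit.n_obs = 6
        assert lack_of_fit(fit, ds) == pytest.approx(1.0, abs=1e-6)

    def test_unavailable_without_replication(self):
        ds = dataset_from_values({0.0: [1.0], 5.0: [0.8], 20.0: [0.4]})
        fit = from_params("EXD.3", c=0.1, e=12.0)
        fit.rss, fit.n_obs = 0.01, 3
        assert lack_of_fit(fit, ds) is None


class TestAIC:
    def _stub(self, family, n, rss, **params):
        fit = from_params(family, **params)
        fit.n_obs, fit.rss = n, rss
        return fit

    def test_hand_formula(self):
        fit = self._stub("LL.4", 12, 0.03, b=2, c=0.1, e=10)  # p = 3
        expected = 12 * (math.log(2 * math.pi * 0.03 / 12) + 1) + 2 * (3 + 1)
        assert aic(fit) == pytest.approx(expected, abs=1e-10)

    def test_extra_parameter_costs_exactly_two(self):
        f3 = self._stub("LL.4", 12, 0.03, b=2, c=0.1, e=10)       # 3 free
        f4 = self._stub("BC.5", 12, 0.03, b=2, c=0.1, e=10, f=0.01)  # 4 free
        assert aic(f4) - aic(f3) == pytest.approx(2.0)

    def test_zero_rss_sentinel(self):
        fit = self._stub("LL.4", 12, 0.0, b=2, c=0.1, e=10)
        assert aic(fit) == -math.inf


class TestCombinedCriterion:
    @pytest.mark.parametrize("a,lof,expected", [
        (100.0, 0.5, 200.0),
        (-100.0, 0.5, -50.0),
        (42.0, 1.0, 42.0),
        (-42.0, 1.0, -42.0),
        (0.0, 0.7, 0.0),
    ])
    def test_piecewise_values(self, a, lof, expected):
        assert combined_criterion(a, lof) == pytest.approx(expected)

    def test_zero_lof_with_positive_aic_is_worst(self):
        assert combined_criterion(10.0, 0.0) == math.inf

    def test_without_replication_degrades_to_aic(self):
        assert combined_criterion(-12.5, None) == -12.5

    def test_monotone_improving_in_lof_and_aic(self):
        # better (higher) LoF and better (lower) AIC never worsen CC
        lofs = np.linspace(0.05, 1.0, 20)
        for a in (-100.0, -1.0, -0.01, 0.01, 1.0, 100.0):
            ccs = [combined_criterion(a, l) for l in lofs]
            assert all(b <= a_ + 1e-12 for a_, b in zip(ccs, ccs[1:]))
        aics = np.linspace(-200, 200, 41)
        for lof in (0.05, 0.5, 1.0):
            ccs = [combined_criterion(a, lof) for a in aics]
            assert all(b >= a_ - 1e-12 for a_, b in zip(ccs, ccs[1:]))


class TestPlausibility:
    def setup_method(self):
        self.ds = dataset_from_means(
            {0.0: 1.0, 5.0: 0.9, 15.0: 0.6, 50.0: 0.3, 150.0: 0.1})

    def test_overshooting_curve_eliminated(self):
        # hormetic curve peaking ~1.3 while the highest observed mean is 1.0
        fit = from_params("BC.5", b=2.0, c=0.01, e=30.0, f=0.055)
        grid = np.linspace(0, 150, 1000)
        assert float(np.max(fit.predict(grid))) > 1.1
        assert not plausibility_check(fit, self.ds)

    def test_in_range_curve_plausible(self):
        fit = from_params("LL.4", b=2.0, c=0.1, e=30.0)
        assert plausibility_check(fit, self.ds)

    def test_undershooting_curve_eliminated(self):
        ds = dataset_from_means(
            {0.0: 1.0, 5.0: 0.9, 15.0: 0.8, 50.0: 0.7, 150.0: 0.65})
        fit = from_params("LL.4", b=2.0, c=0.01, e=30.0)  # dips to ~0.01
        assert not plausibility_check(fit, ds)


class TestSelectModel:
    def test_noiseless_weibull_round_trip(self, standard_doses):
        spec = simulate.SimCurveSpec("W1.4", {"b": 2.0, "c": 0.05, "e": 50.0},
                                     standard_doses, n_reps=3, noise_sd=0.0)
        ds = simulate.generate_dose_response(spec)
        best = select_model(ds, seed=0)
        grid = np.asarray(standard_doses)
        np.testing.assert_allclose(np.asarray(best.predict(grid)),
                                   spec.curve(grid), atol=1e-3)

    def test_monotone_data_never_selects_hormesis(self, standard_doses):
        # shallow slope: every consecutive change is either > 15% or a run
        # too short to read as a plateau, so the data classify Decreasing
        spec = simulate.SimCurveSpec("LL.4", {"b": 1.2, "c": 0.1, "e": 30.0},
                                     standard_doses, n_reps=4, noise_sd=0.02,
                                     seed=2)
        ds = simulate.generate_dose_response(spec)
        assert categorize(ds) == "Decreasing"
        best = select_model(ds, seed=0)
        assert "f" not in best.spec.free_params
        assert "f" not in best.spec.fixed_params

    def test_hormetic_peak_recovered_near_M(self):
        doses = (0.0, 2.0, 6.0, 20.0, 60.0, 200.0)
        spec = simulate.SimCurveSpec(
            "RBC.5", {"b": 2.0, "c": 0.05, "f": 0.1, "M": 6.0},
            doses, n_reps=4, noise_sd=0.02, seed=4)
        peak = float(np.max(spec.curve(np.linspace(0.01, 200, 2000))))
        assert peak > 1.2  # clearly hormetic truth
        ds = simulate.generate_dose_response(spec)
        best = select_model(ds, seed=0)
        assert best.category == "Growth"
        grid = np.linspace(0.0, 200.0, 401)
        fitted_peak_dose = grid[int(np.argmax(np.asarray(best.predict(grid))))]
        # within one dose-ladder step of the true peak at 6 (neighbors 2 and 20)
        assert 2.0 < fitted_peak_dose < 20.0

    def test_selected_fit_is_flagged(self, standard_doses):
        spec = simulate.SimCurveSpec("LL.4", {"b": 2.0, "c": 0.1, "e": 50.0},
                                     standard_doses, n_reps=4, noise_sd=0.02,
                                     seed=9)
        best = select_model(simulate.generate_dose_response(spec), seed=0)
        assert best.plausible is not None
        assert best.converged
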