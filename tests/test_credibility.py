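"""Jackknife intervals, prediction error rates, sensitivity analysis."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from emt import time_grid
from emt.consistency import FitSettings
from emt.credibility import (
    DeleteDJackknife,
    DsaProblem,
    PredictionErrorAnalysis,
    QUARTERLY_REFIT_INTERVAL,
    SensitivityAnalysis,
    blind_guessing_threshold,
    n_predictions,
    rms_error,
    shortest_interval,
    subsample_size,
    zeta_hat,
)
from emt.data import generate_synthetic_history
from emt.influence import simulate


class TestSubsampleSize:
    def test_case_study_value(self):
        assert subsample_size(546, 0.97) == 451

    def test_minimal_sample(self):
        assert subsample_size(2, 0.5) == 1

    def test_large_n_against_high_precision_power(self):
        from decimal import Decimal, getcontext

        getcontext().prec = 60
        oracle = int(Decimal(10_000) ** Decimal("0.9"))
        assert subsample_size(10_000, 0.9) == oracle

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            subsample_size(1, 0.9)
        with pytest.raises(ValueError):
            subsample_size(100, 1.0)

    @given(st.integers(2, 5000), st.floats(0.2, 0.99))
    @hsettings(max_examples=150, deadline=None)
    def test_monotone_and_consistent(self, n, tau):
        r = subsample_size(n, tau)
        assert 1 <= r < n
        assert subsample_size(n + 1, tau) >= r
        assert subsample_size(n, min(tau + 0.005, 0.995)) >= r

    def test_consistency_condition_r_over_n_vanishes(self):
        # r = floor(n^tau), tau < 1  =>  r/n -> 0 along a growing grid
        ratios = [subsample_size(n, 0.97) / n for n in (10**3, 10**5, 10**7, 10**9)]
        assert all(b < a for a, b in zip(ratios, ratios[1:]))


class TestShortestInterval:
    def test_worked_example(self):
        # replicates {0.1, 0.2, 0.25, 0.9, 1.0}, alpha 0.5 -> window of 3
        lo, hi = shortest_interval([0.1, 0.2, 0.25, 0.9, 1.0], alpha=0.5)
        assert (lo, hi) == (0.1, 0.25)

    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=25),
           st.floats(0.05, 0.9))
    @hsettings(max_examples=150, deadline=None)
    def test_matches_exhaustive_window_enumeration(self, values, alpha):
        v = sorted(values)
        k = max(1, min(int(np.ceil((1 - alpha) * len(v))), len(v)))
        candidates = [(v[i + k - 1] - v[i], v[i], v[i + k - 1])
                      for i in range(len(v) - k + 1)]
        width, lo, hi = min(candidates)  # tuple order: minimal width, lowest lo
        got = shortest_interval(values, alpha)
        assert got == (lo, hi)

    def test_sorting_invariance(self):
        vals = [0.4, 0.1, 0.9, 0.3, 0.2]
        assert shortest_interval(vals, 0.5) == shortest_interval(sorted(vals), 0.5)


class TestJackknife:
    def test_identical_replicates_zero_width(self):
        jk = DeleteDJackknife(lambda s: {"c": 1.0}, np.arange(30), tau=0.8,
                              n_jack=10, alpha=0.5, seed=0)
        res = jk.fit()
        lo, hi = res.interval("c")
        assert lo == hi == 1.0

    def test_interval_contains_enough_replicates(self):
        rng = np.random.default_rng(1)
        jk = DeleteDJackknife(lambda s: {"m": float(np.mean(s))},
                              rng.normal(size=60), tau=0.8, n_jack=20,
                              alpha=0.5, seed=2)
        res = jk.fit()
        lo, hi = res.interval("m")
        inside = ((res.replicates["m"] >= lo) & (res.replicates["m"] <= hi)).sum()
        assert inside >= int(np.ceil(0.5 * 20))

    def test_failing_replicates_dropped_with_survivors(self):
        calls = {"n": 0}

        def estimator(s):
            calls["n"] += 1
            if calls["n"] in (2, 3):  # fail the retry too
                raise RuntimeError("unstable subsample")
            return {"m": float(np.mean(s))}

        jk = DeleteDJackknife(estimator, np.arange(40), tau=0.8, n_jack=5,
                              alpha=0.5, seed=3)
        res = jk.fit()
        assert res.dropped == 1
        assert len(res.replicates) == 4


class TestPredictionErrorEstimators:
    def test_perfect_simulator_zero_error(self):
        assert zeta_hat([3, 2], [3, 2]) == 0.0

    def test_two_step_worked_example(self):
        # match ratios 1/2 and 2/2 -> zeta-hat = ((1-0.5) + 0)/2 = 0.25
        assert zeta_hat([1, 2], [2, 2]) == pytest.approx(0.25, abs=1e-12)

    def test_naive_forecast_worked_example(self):
        # series (5, 7, 6): naive forecasts (5, 7) vs observed (7, 6)
        assert rms_error([7, 6], [5, 7]) == pytest.approx(np.sqrt(2.5), abs=1e-12)

    def test_quarterly_default(self):
        assert round(QUARTERLY_REFIT_INTERVAL, 4) == 0.2308

    def test_n_predictions_formula(self):
        assert n_predictions(3.0, 0.3, 0.2308) == int(np.floor((3 - 1 - 0.3) / 0.2308)) + 1

    def test_blind_guessing_threshold(self):
        assert blind_guessing_threshold(3) == pytest.approx(2 / 3)

    def test_schedule_past_data_errors(self, one_group):
        sim, b = one_group
        grid = time_grid(2019.0, 2019.6)
        hist = generate_synthetic_history(sim, b, grid, seed=1)
        pe = PredictionErrorAnalysis(sim, hist.dataset, b, s=2.0, v=0.2308)
        with pytest.raises(ValueError):
            pe.fit()


class TestRollingRefit:
    def test_toy_pipeline_outputs(self, one_group):
        sim, b = one_group
        grid = time_grid(2019.0, 2021.0)
        hist = generate_synthetic_history(sim, b, grid, seed=7)
        settings = FitSettings(cH=0.99, decision_mc=50, eco_mc=30, report_mc=100,
                               max_evals=6, steps=0.05, tol=0.03, seed=2)
        res = PredictionErrorAnalysis(sim, hist.dataset, b, s=0.3,
                                      v=QUARTERLY_REFIT_INTERVAL,
                                      settings=settings).fit()
        assert 0.0 <= res.zeta <= 1.0
        assert res.epsilon["cheetah"] >= 0.0
        assert res.delta["cheetah"] >= 0.0
        assert res.blind_thresholds["krr"] == pytest.approx(2 / 3)
        assert res.n_pred == n_predictions(hist.dataset.T_D - 2019.0, 0.3,
                                           QUARTERLY_REFIT_INTERVAL)


class TestSensitivityAnalysis:
    def _fit(self, sim, b_h, responses_at, plausibility, seed=3):
        grid = time_grid(2019.0, 2020.5)
        rec = simulate(sim, responses_at, grid, mc_reals=200, seed=4, decision_mc=200)
        resp = [("cheetah", float(t), float(v))
                for t, v in zip(rec.times[::6], rec.metric_means[::6, 0])]
        problem = DsaProblem(
            responses={"krr": [("farm", "ecosys")]},
            forbidden={"krr": [("poach", "ecosys")]},
            metric_responses=resp, variable_block="eco",
            plausibility=plausibility, time_grid=grid, cH=0.1,
        )
        settings = FitSettings(decision_mc=50, eco_mc=30, report_mc=100,
                               max_evals=40, steps=0.05, tol=0.02, seed=seed)
        return SensitivityAnalysis(problem, sim, b_h, settings=settings).fit()

    def test_fixed_point_when_scenario_matches_hypothesis(self, one_group):
        # responses generated by the simulator at B_H itself (with the same
        # complement-action filtering) cannot improve on B_H
        sim, b_h = one_group
        grid = time_grid(2019.0, 2020.0)
        rec = simulate(sim, b_h, grid, mc_reals=100, seed=5, decision_mc=100)
        resp = [("cheetah", float(t), float(v))
                for t, v in zip(rec.times, rec.metric_means[:, 0])]
        problem = DsaProblem(metric_responses=resp, variable_block="eco",
                             time_grid=grid, cH=0.1)
        settings = FitSettings(decision_mc=100, eco_mc=100, report_mc=100,
                               max_evals=30, steps=0.05, tol=0.03, seed=5)
        res = SensitivityAnalysis(problem, sim, b_h, settings=settings).fit()
        eco = res.table[res.table["parameter"].str.startswith("ecosys")]
        assert (eco["abs_diff"] < 1e-9).all()

    def test_implausible_change_rejects_skeptic(self, one_group):
        # forcing a no-poaching world to reproduce the poached trajectory
        # demands a survival-rate change far outside its plausible band
        sim, b_h = one_group
        res = self._fit(sim, b_h, b_h,
                        {"ecosys.cheetah.b[prev_cheetah]": (0.83, 0.87)})
        assert not res.supported
        assert res.difference > 0

    def test_plausible_change_supports_skeptic(self, one_group):
        # a generous plausibility band covering the DSA value flips the verdict
        sim, b_h = one_group
        res = self._fit(sim, b_h, b_h,
                        {"ecosys.cheetah.b[prev_cheetah]": (0.0, 1.0),
                         "ecosys.cheetah.b0": (-100.0, 100.0),
                         "ecosys.cheetah.b[poaching]": (-100.0, 100.0),
                         "ecosys.cheetah.scale": (0.0, 100.0)})
        assert res.supported
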