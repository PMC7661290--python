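import numpy as np
import pytest
from scipy import optimize, stats

import fishpass as fp
from fishpass.survival import (
    RiskSetData,
    apply_scaling,
    build_simulation_template,
    ph_assumption_check,
)
from conftest import make_risk_data


def enumerate_breslow_loglik(beta, durations, event, x):
    """Brute-force Breslow partial log-likelihood for single-interval
    subjects (time origin 0, no ties)."""
    beta = np.atleast_1d(beta)
    durations = np.asarray(durations, dtype=float)
    x = np.asarray(x, dtype=float).reshape(len(durations), -1)
    ll = 0.0
    for i in np.flatnonzero(event):
        risk = durations >= durations[i]
        eta = x @ beta
        ll += eta[i] - np.log(np.sum(np.exp(eta[risk])))
    return ll


class TestBuildCountingProcess:
    def _cov(self, days=4):
        return fp.CovariateSeries(
            season_days=days,
            temperature=np.linspace(10, 13, days),
            spill=np.linspace(1, 4, days),
            daily_count={("TD", "chinook"): np.array([100.0, 150.0, 151.0, 80.0])[:days]},
        )

    def test_exposure_conserved_across_midnight(self):
        # 30 h of exposure spanning one midnight, daily covariates only
        fish = [
            fp.FishRecord(
                "f1", "chinook", t_tailrace_entry=10.0, t_first_fishway_entry=40.0
            )
        ]
        data = fp.build_counting_process(fish, self._cov(), "finding", ("temperature",))
        assert data.n_intervals >= 2
        assert data.exposure().sum() == pytest.approx(30.0)
        assert data.n_events == 1
        assert data.event[-1]

    def test_threshold_indicator_at_150(self):
        # counts by day: 100, 150, 151 -> indicator 1, 1, 0
        fish = [
            fp.FishRecord(
                "f1", "chinook", t_tailrace_entry=0.0, t_first_fishway_entry=70.0
            )
        ]
        data = fp.build_counting_process(
            fish, self._cov(), "finding", ("temperature", "count"), count_threshold=150.0
        )
        j = data.covariates.index("count_thresh")
        jc = data.covariates.index("count")
        by_day = {int(s // 24): v for s, v in zip(data.start, data.X[:, j])}
        assert by_day == {0: 1.0, 1: 1.0, 2: 0.0}
        assert {int(s // 24): v for s, v in zip(data.start, data.X[:, jc])} == {
            0: 100.0, 1: 150.0, 2: 151.0,
        }

    def test_zero_fish_empty_no_error(self):
        data = fp.build_counting_process([], self._cov(), "finding", ("temperature",))
        assert data.n_intervals == 0
        assert data.n_subjects == 0

    def test_missing_timestamps_excluded_and_counted(self):
        fish = [
            fp.FishRecord("f1", "chinook", t_tailrace_entry=0.0),
            fp.FishRecord(
                "f2", "chinook", t_tailrace_entry=0.0, t_first_fishway_entry=10.0
            ),
        ]
        data = fp.build_counting_process(fish, self._cov(), "finding", ("temperature",))
        assert data.n_subjects == 1
        assert data.exclusions == {"missing_timestamp": 1}

    def test_outside_coverage_names_fish(self):
        fish = [
            fp.FishRecord(
                "f9", "chinook", t_tailrace_entry=90.0, t_first_fishway_entry=130.0
            )
        ]
        with pytest.raises(fp.DataError, match="f9"):
            fp.build_counting_process(fish, self._cov(), "finding", ("temperature",))

    def test_diel_splits_at_window_edges(self):
        fish = [
            fp.FishRecord(
                "f1", "chinook", t_tailrace_entry=0.0, t_first_fishway_entry=24.0
            )
        ]
        data = fp.build_counting_process(fish, self._cov(), "finding", ("diel",))
        assert data.exposure().sum() == pytest.approx(24.0)
        # exposure with diel == 1 spans exactly the 06:00-18:00 window
        assert data.exposure()[data.X[:, 0] == 1.0].sum() == pytest.approx(12.0)


class TestStandardize:
    def test_two_point_example(self):
        data = make_risk_data([1.0, 1.0], [True, True], [[0.0], [10.0]], ["x"])
        out, record = fp.standardize(data)
        assert out.X[:, 0] == pytest.approx([-1.0, 1.0])
        assert record.center["x"] == pytest.approx(5.0)
        assert record.scale["x"] == pytest.approx(5.0)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        data = make_risk_data(
            rng.exponential(size=20) + 0.1,
            np.ones(20, bool),
            rng.normal(size=(20, 2)),
            ["a", "b"],
        )
        once, _ = fp.standardize(data)
        # re-fitting scaling on already-standardized values is a no-op
        again, _ = fp.standardize(
            make_risk_data(once.stop, once.event, once.X, ["a", "b"])
        )
        assert np.allclose(once.X, again.X, atol=1e-12)

    def test_binary_untouched(self):
        data = make_risk_data(
            [1.0, 2.0, 3.0], [True] * 3, [[0.0], [1.0], [0.0]], ["diel"]
        )
        out, record = fp.standardize(data)
        assert np.array_equal(out.X[:, 0], data.X[:, 0])
        assert "diel" in record.binary

    def test_zero_variance_raises(self):
        data = make_risk_data([1.0, 2.0], [True, True], [[3.0], [3.0]], ["x"])
        with pytest.raises(fp.DegenerateCovariateError):
            fp.standardize(data)


class TestFitPH:
    def test_three_subject_grid_oracle(self):
        # covariate (1, 0, 2) with events in duration order: the enumerated
        # partial likelihood has an interior maximum
        durations = [1.0, 2.0, 3.0]
        event = [True] * 3
        x = [[1.0], [0.0], [2.0]]
        data = make_risk_data(durations, event, x, ["x"])
        fit = fp.fit_ph(data)
        oracle = optimize.minimize_scalar(
            lambda b: -enumerate_breslow_loglik(b, durations, event, x),
            bounds=(-10, 10),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.beta[0] == pytest.approx(oracle.x, abs=1e-6)
        assert fit.loglik == pytest.approx(-oracle.fun, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_five_subject_oracle(self, seed):
        rng = np.random.default_rng(seed)
        durations = rng.exponential(size=5) + 0.05
        event = np.ones(5, bool)
        x = rng.normal(size=(5, 1))
        data = make_risk_data(durations, event, x, ["x"])
        fit = fp.fit_ph(data)
        oracle = optimize.minimize_scalar(
            lambda b: -enumerate_breslow_loglik(b, durations, event, x),
            bounds=(-20, 20),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.beta[0] == pytest.approx(oracle.x, abs=1e-6)

    def test_symmetric_dataset_gives_zero(self):
        # negating the covariate and swapping subject roles leaves the data
        # invariant, so the estimate must be 0
        data = make_risk_data(
            [1.0, 1.0, 2.0, 2.0],
            [True] * 4,
            [[1.0], [-1.0], [1.0], [-1.0]],
            ["x"],
        )
        fit = fp.fit_ph(data)
        assert abs(fit.beta[0]) < 1e-8

    def test_empty_covariate_set_closed_form(self):
        data = make_risk_data([1.0, 2.0, 3.0], [True] * 3, [[0.0]] * 3, ["x"])
        fit = fp.fit_ph(data, covariate_set=[])
        # with exp(X beta) = 1 the log PL is -sum log(risk-set size)
        assert fit.loglik == pytest.approx(-(np.log(3) + np.log(2) + np.log(1)))
        assert fit.aicc == pytest.approx(-2 * fit.loglik)

    def test_score_converged(self):
        rng = np.random.default_rng(3)
        n = 60
        x = rng.normal(size=(n, 2))
        t = rng.exponential(np.exp(-0.5 * x[:, 0]))
        data = make_risk_data(t, np.ones(n, bool), x, ["a", "b"])
        fit = fp.fit_ph(data)
        pl = fp.survival._PartialLikelihood(data.start, data.stop, data.event, x)
        _, score, _ = pl.quantities(fit.beta)
        assert np.max(np.abs(score)) < 1e-6

    def test_likelihood_monotone_in_covariates(self):
        rng = np.random.default_rng(4)
        n = 80
        x = rng.normal(size=(n, 2))
        t = rng.exponential(np.exp(-0.7 * x[:, 0]))
        data = make_risk_data(t, np.ones(n, bool), x, ["a", "b"])
        ll0 = fp.fit_ph(data, covariate_set=[]).loglik
        ll1 = fp.fit_ph(data, covariate_set=["a"]).loglik
        ll2 = fp.fit_ph(data, covariate_set=["a", "b"]).loglik
        assert ll0 <= ll1 + 1e-9
        assert ll1 <= ll2 + 1e-9

    def test_separation_raises(self):
        # perfect ordering of events by covariate -> monotone likelihood
        data = make_risk_data(
            [1.0, 2.0, 3.0, 4.0],
            [True] * 4,
            [[3.0], [2.0], [1.0], [0.0]],
            ["x"],
        )
        with pytest.raises(fp.ConvergenceError):
            fp.fit_ph(data)

    def test_collinear_named(self):
        rng = np.random.default_rng(5)
        n = 30
        a = rng.normal(size=n)
        X = np.column_stack([a, 2 * a])
        data = make_risk_data(rng.exponential(size=n), np.ones(n, bool), X, ["a", "b"])
        with pytest.raises(fp.RankDeficiencyError):
            fp.fit_ph(data)

    def test_no_events_raises(self):
        data = make_risk_data([1.0], [False], [[0.0]], ["x"])
        with pytest.raises(fp.DataError):
            fp.fit_ph(data)

    def test_efron_matches_breslow_without_ties(self):
        rng = np.random.default_rng(6)
        n = 40
        x = rng.normal(size=(n, 1))
        t = rng.exponential(np.exp(-0.4 * x[:, 0]))
        data = make_risk_data(t, np.ones(n, bool), x, ["x"])
        b1 = fp.fit_ph(data, ties="breslow").beta[0]
        b2 = fp.fit_ph(data, ties="efron").beta[0]
        assert b1 == pytest.approx(b2, abs=1e-8)

    def test_time_varying_oracle(self):
        # two-interval subjects: verify against an explicit risk-set enumeration
        subj = np.array([0, 0, 1, 1, 2])
        start = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        stop = np.array([1.0, 2.5, 1.0, 3.0, 0.8])
        event = np.array([False, True, False, True, True])
        X = np.array([[0.0], [1.0], [1.0], [0.0], [0.5]])
        import pandas as pd

        groups = pd.DataFrame(
            {
                "fish_id": ["a", "b", "c"],
                "species": "s", "run": "-", "dam": "d", "fishway": "f",
                "entry_hour": 0.0,
            }
        )
        data = RiskSetData(
            subject=subj, start=start, stop=stop, event=event, X=X,
            covariates=["x"], groups=groups,
        )

        def neg_ll(b):
            # events at t=0.8 (risk: subj0 x=0, subj1 x=1, subj2 x=0.5),
            # t=2.5 (risk: subj0 x=1, subj1 x=0), t=3.0 (risk: subj1 x=0)
            ll = 0.0
            ll += 0.5 * b - np.log(np.exp(0.0) + np.exp(b) + np.exp(0.5 * b))
            ll += 1.0 * b - np.log(np.exp(b) + np.exp(0.0))
            ll += 0.0 - np.log(np.exp(0.0))
            return -ll

        oracle = optimize.minimize_scalar(
            neg_ll, bounds=(-10, 10), method="bounded", options={"xatol": 1e-10}
        )
        fit = fp.fit_ph(data)
        assert fit.beta[0] == pytest.approx(oracle.x, abs=1e-6)


class TestBreslowBaseline:
    def test_nelson_aalen_hand_example(self):
        # events at t=1 (risk set 3) and t=2 (risk set 2)
        data = make_risk_data(
            [1.0, 2.0, 2.5], [True, True, False], [[0.0]] * 3, ["x"]
        )
        fit = fp.fit_ph(data, covariate_set=[])
        base = fp.breslow_baseline(fit, data)
        assert base.times == pytest.approx([1.0, 2.0])
        assert base.increments == pytest.approx([1 / 3, 1 / 2])
        assert base.cumhaz(np.array([2.0]))[0] == pytest.approx(5 / 6)

    def test_nelson_aalen_equivalence_random(self, rng):
        n = 50
        t = rng.exponential(size=n)
        data = make_risk_data(t, np.ones(n, bool), np.zeros((n, 1)), ["x"])
        fit = fp.fit_ph(data, covariate_set=[])
        base = fp.breslow_baseline(fit, data)
        # Nelson-Aalen: increment 1/(number at risk) at each event time
        order = np.sort(t)
        expected = 1.0 / (n - np.arange(n))
        assert base.increments == pytest.approx(expected)
        assert base.times == pytest.approx(order)

    def test_scale_invariance(self):
        # doubling every exp(X beta) halves every increment
        data = make_risk_data(
            [1.0, 2.0, 3.0], [True] * 3, [[1.0], [1.0], [1.0]], ["x"]
        )
        fit = fp.fit_ph(data, covariate_set=[])
        base0 = fp.breslow_baseline(fit, data)
        fit2 = fp.PHFit(
            covariates=["x"], beta=np.array([np.log(2.0)]),
            cov_matrix=np.eye(1), loglik=0.0, loglik_null=0.0, aicc=0.0,
            n_subjects=3, n_events=3, scaling=None, ties="breslow",
            n_iter=0, converged=True,
        )
        base2 = fp.breslow_baseline(fit2, data)
        assert base2.increments == pytest.approx(base0.increments / 2.0)

    def test_no_events_empty(self):
        data = make_risk_data([1.0, 2.0], [False, False], [[0.0], [0.0]], ["x"])
        fit = fp.PHFit(
            covariates=[], beta=np.zeros(0), cov_matrix=np.zeros((0, 0)),
            loglik=0.0, loglik_null=0.0, aicc=0.0, n_subjects=2, n_events=0,
            scaling=None, ties="breslow", n_iter=0, converged=True,
        )
        base = fp.breslow_baseline(fit, data)
        assert base.times.size == 0
        assert base.cumhaz(np.array([10.0]))[0] == 0.0


class TestSimulateEventTimes:
    def test_round_trip_recovery(self):
        # fit, simulate from the fit, refit: estimates agree within 3 SE
        rng = np.random.default_rng(7)
        hits = 0
        for rep in range(20):
            n = 300
            x = rng.normal(size=(n, 1))
            t = rng.exponential(np.exp(-0.5 * x[:, 0]))
            data = make_risk_data(t, np.ones(n, bool), x, ["x"])
            fit = fp.fit_ph(data)
            template = make_risk_data(np.full(n, 1e4), np.zeros(n, bool), x, ["x"])
            base = fp.breslow_baseline(fit, data)
            sim = fp.simulate_event_times(fit, base, template, seed=rng)
            new = template.with_event_times(sim.times, sim.resolved)
            refit = fp.fit_ph(new)
            if abs(refit.beta[0] - fit.beta[0]) <= 3 * refit.se[0]:
                hits += 1
        assert hits >= 17

    def test_exposure_conservation_under_splitting(self):
        # splitting template intervals more finely never changes total
        # exposure nor the simulated draw (same seed)
        n = 50
        rng = np.random.default_rng(8)
        x = rng.normal(size=(n, 1))
        t = rng.exponential(np.exp(0.4 * x[:, 0])) + 0.1
        data = make_risk_data(t, np.ones(n, bool), x, ["x"])
        fit = fp.fit_ph(data)
        base = fp.breslow_baseline(fit, data)
        coarse = make_risk_data(np.full(n, 100.0), np.zeros(n, bool), x, ["x"])
        # split each subject at its midpoint
        import pandas as pd

        fine = RiskSetData(
            subject=np.repeat(np.arange(n), 2),
            start=np.column_stack([np.zeros(n), np.full(n, 50.0)]).ravel(),
            stop=np.column_stack([np.full(n, 50.0), np.full(n, 100.0)]).ravel(),
            event=np.zeros(2 * n, bool),
            X=np.repeat(x, 2, axis=0),
            covariates=["x"],
            groups=coarse.groups,
        )
        assert fine.exposure().sum() == pytest.approx(coarse.exposure().sum())
        s1 = fp.simulate_event_times(fit, base, coarse, seed=42)
        s2 = fp.simulate_event_times(fit, base, fine, seed=42)
        assert np.allclose(s1.times, s2.times)


class TestPHAssumptionCheck:
    def test_calibrated_under_ph(self):
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            n = 60
            x = rng.normal(size=(n, 1))
            t = rng.exponential(np.exp(-0.5 * x[:, 0]))
            data = make_risk_data(t, np.ones(n, bool), x, ["x"])
            fit = fp.fit_ph(data)
            res = ph_assumption_check(fit, data, n_perm=99, seed=rng)
            rejections += res.p_value[0] <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_power_against_time_varying_effect(self):
        rng = np.random.default_rng(10)
        rejections = 0
        n_rep = 20
        for _ in range(n_rep):
            n = 300
            x = rng.binomial(1, 0.5, size=n).astype(float)
            # x=1 hazard rises steeply with time (Weibull shape 3) while
            # x=0 stays exponential: a strongly time-increasing effect
            t = np.where(x == 1, rng.weibull(3.0, size=n), rng.exponential(size=n))
            data = make_risk_data(t, np.ones(n, bool), x[:, None], ["x"])
            fit = fp.fit_ph(data)
            res = ph_assumption_check(fit, data, n_perm=99, seed=rng)
            rejections += res.p_value[0] <= 0.05
        assert rejections / n_rep > 0.5

    def test_too_few_events_skipped(self):
        data = make_risk_data(
            [1.0, 2.0, 3.0], [True] * 3, [[1.0], [0.0], [2.0]], ["x"]
        )
        fit = fp.fit_ph(data)
        with pytest.warns(UserWarning, match="skipped"):
            res = ph_assumption_check(fit, data)
        assert res.skipped
        assert np.isnan(res.p_value).all()


class TestTemplateAndScaling:
    def test_template_matches_subject_order(self):
        cov = fp.CovariateSeries(
            season_days=10,
            temperature=np.linspace(10, 12, 10),
            spill=np.ones(10),
            daily_count={("TD", "chinook"): np.arange(10.0)},
        )
        fish = [
            fp.FishRecord(
                f"f{i}", "chinook", t_tailrace_entry=30.0 * i,
                t_first_fishway_entry=30.0 * i + 5.0,
            )
            for i in range(5)
        ]
        data = fp.build_counting_process(fish, cov, "finding", ("temperature", "count"))
        std, record = fp.standardize(data)
        template = build_simulation_template(
            fish, cov, "finding", ("temperature", "count"), scaling=record
        )
        assert list(template.groups["fish_id"]) == list(std.groups["fish_id"])
        assert not template.event.any()
        # template end extends beyond the observed event times
        assert template.exposure().sum() > std.exposure().sum()

    def test_apply_scaling_round_trip(self):
        data = make_risk_data([1.0, 2.0], [True, True], [[0.0], [10.0]], ["x"])
        std, record = fp.standardize(data)
        again = apply_scaling(std, record)
        assert np.allclose(again.X, std.X)
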