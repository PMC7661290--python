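import numpy as np
import pytest

import fishpass as fp
from fishpass.records import HOURS_PER_DAY


def _basic_truth(**kw):
    defaults = dict(
        seed=1,
        season_days=30,
        cohorts=[fp.CohortSpec(arrival_total=100.0)],
        density_mode="none",
    )
    defaults.update(kw)
    return fp.SimulationTruth(**defaults)


class TestGenerateEnvironment:
    def test_zero_noise_gives_exact_sinusoid(self):
        truth = _basic_truth(temp_ar_sd=0.0)
        env = fp.generate_environment(truth)
        days = np.arange(truth.season_days)
        expected = truth.temp_mean + truth.temp_amplitude * np.sin(
            2 * np.pi * days / truth.temp_period_days
        )
        assert env.temperature == pytest.approx(expected)

    def test_same_seed_identical(self):
        t = _basic_truth()
        e1, e2 = fp.generate_environment(t), fp.generate_environment(t)
        assert np.array_equal(e1.temperature, e2.temperature)
        assert np.array_equal(e1.spill, e2.spill)
        for k in e1.daily_count:
            assert np.array_equal(e1.daily_count[k], e2.daily_count[k])

    def test_different_seed_differs(self):
        e1 = fp.generate_environment(_basic_truth(seed=1))
        e2 = fp.generate_environment(_basic_truth(seed=2))
        assert not np.array_equal(e1.temperature, e2.temperature)

    def test_diel_sums_to_12_per_day(self):
        env = fp.generate_environment(_basic_truth())
        hours = np.arange(0, env.season_hours)
        # one-hour grid: the 06:00-18:00 window holds 12 hours per day
        diel = env.value("diel", hours + 0.5)
        per_day = diel.reshape(env.season_days, 24).sum(axis=1)
        assert np.all(per_day == 12.0)

    def test_nonpositive_season_rejected(self):
        with pytest.raises(fp.ConfigurationError):
            _basic_truth(season_days=0)


class TestGenerateCohort:
    def test_beta_zero_constant_hazard_exponential_mean(self):
        rate = 0.1
        truth = _basic_truth(
            season_days=60,
            cohorts=[fp.CohortSpec(arrival_total=2000.0, arrival_peak_day=20.0,
                                   arrival_sd_days=5.0)],
            find_baseline=rate,
            fixed_arrivals=True,
            max_followup_hours=600.0,
        )
        env = fp.generate_environment(truth)
        cohort = fp.generate_cohort(truth, env)
        delays = np.array(
            [
                f.t_first_fishway_entry - f.t_tailrace_entry
                for f in cohort
                if f.t_first_fishway_entry is not None
            ]
        )
        n = delays.size
        assert n > 1800  # nearly all resolve within follow-up
        se = (1 / rate) / np.sqrt(n)
        assert abs(delays.mean() - 1 / rate) < 3 * se

    def test_default_commit_intercept_is_43_percent(self):
        p = 1.0 / (1.0 + np.exp(-fp.DEFAULT_COMMIT_INTERCEPT))
        assert p == pytest.approx(0.43)
        truth = _basic_truth(
            cohorts=[fp.CohortSpec(arrival_total=4000.0)],
            fixed_arrivals=True,
        )
        env = fp.generate_environment(truth)
        cohort = fp.generate_cohort(truth, env)
        flags = [f.committed_first_attempt for f in cohort
                 if f.committed_first_attempt is not None]
        assert abs(np.mean(flags) - 0.43) < 3 * np.sqrt(0.43 * 0.57 / len(flags))

    def test_doubling_hazard_halves_median(self):
        kw = dict(
            season_days=60,
            cohorts=[fp.CohortSpec(arrival_total=3000.0, arrival_peak_day=20.0,
                                   arrival_sd_days=5.0)],
            fixed_arrivals=True,
            max_followup_hours=600.0,
        )
        t1 = _basic_truth(find_baseline=0.05, **kw)
        t2 = _basic_truth(find_baseline=0.10, **kw)
        env = fp.generate_environment(t1)

        def med(truth):
            cohort = fp.generate_cohort(truth, env, rng=np.random.default_rng(7))
            d = [
                f.t_first_fishway_entry - f.t_tailrace_entry
                for f in cohort
                if f.t_first_fishway_entry is not None
            ]
            return np.median(d)

        ratio = med(t2) / med(t1)
        assert 0.45 < ratio < 0.55

    def test_timestamps_ordered_and_commit_consistent(self):
        truth = _basic_truth(beta_find={"diel": 1.0, "temperature": 0.3})
        env = fp.generate_environment(truth)
        for f in fp.generate_cohort(truth, env):
            f.validate()
            if f.committed_first_attempt is True:
                assert f.t_first_fishway_entry == f.t_last_fishway_entry

    def test_stage_durations_sum_for_committed_fish(self):
        truth = _basic_truth()
        env = fp.generate_environment(truth)
        seen = 0
        for f in fp.generate_cohort(truth, env):
            if f.committed_first_attempt and f.t_fishway_exit is not None:
                total = f.t_fishway_exit - f.t_tailrace_entry
                parts = (f.t_first_fishway_entry - f.t_tailrace_entry) + (
                    f.t_fishway_exit - f.t_last_fishway_entry
                )
                assert total == pytest.approx(parts)
                seen += 1
        assert seen > 10

    def test_mismatched_season_rejected(self):
        truth = _basic_truth()
        env = fp.generate_environment(_basic_truth(season_days=10))
        with pytest.raises(fp.DataError):
            fp.generate_cohort(truth, env)

    def test_dropout_leaves_valid_records(self):
        truth = _basic_truth(dropout=0.3)
        env = fp.generate_environment(truth)
        cohort = fp.generate_cohort(truth, env)
        missing = sum(f.t_tailrace_entry is None for f in cohort)
        assert missing > 0
        for f in cohort:
            f.validate()

    def test_latent_density_speeds_up_finding(self):
        # with a positive latent-density coefficient, scaling up arrivals
        # lowers mean finding time (3 intensity levels)
        means = []
        for level, total in enumerate([30.0, 90.0, 270.0]):
            delays = []
            for rep in range(50):
                truth = _basic_truth(
                    seed=rep,
                    season_days=20,
                    cohorts=[fp.CohortSpec(arrival_total=total)],
                    density_mode="latent",
                    beta_find={"density": 0.8},
                    find_baseline=0.06,
                    latent_center=8.0,
                    latent_scale=4.0,
                )
                env = fp.generate_environment(truth)
                cohort = fp.generate_cohort(
                    truth, env, rng=np.random.default_rng(1000 * level + rep)
                )
                delays.extend(
                    f.t_first_fishway_entry - f.t_tailrace_entry
                    for f in cohort
                    if f.t_first_fishway_entry is not None
                )
            means.append(np.mean(delays))
        assert means[0] > means[1] > means[2]


class TestDeriveDailyCounts:
    def _fish(self, exits):
        return [
            fp.FishRecord(
                f"f{i}", "chinook", t_tailrace_entry=0.0,
                t_first_fishway_entry=1.0, t_last_fishway_entry=1.0,
                t_fishway_exit=float(t), committed_first_attempt=True,
            )
            for i, t in enumerate(exits)
        ]

    def test_empty_cohort_all_zero(self):
        counts = fp.derive_daily_counts([], season_days=5)
        assert counts == {}

    def test_conservation_zero_noise_zero_lag(self):
        fish = self._fish([3.0, 5.0, 20.0])
        counts = fp.derive_daily_counts(fish, season_days=5)
        assert counts[("TD", "chinook")][0] == 3.0
        assert counts[("TD", "chinook")].sum() == 3.0

    def test_lag_24h_shifts_series_one_day(self):
        fish = self._fish([3.0, 30.0, 50.0, 70.0])
        c0 = fp.derive_daily_counts(fish, season_days=10)[("TD", "chinook")]
        c24 = fp.derive_daily_counts(fish, season_days=10, lag=24.0)[("TD", "chinook")]
        assert np.array_equal(c24[1:], c0[:-1])
        assert c24[0] == 0.0

    def test_total_conserved_over_generated_cohort(self):
        truth = _basic_truth()
        env = fp.generate_environment(truth)
        cohort = fp.generate_cohort(truth, env)
        counts = fp.derive_daily_counts(cohort, season_days=truth.season_days)
        n_exits = sum(f.t_fishway_exit is not None for f in cohort)
        assert sum(c.sum() for c in counts.values()) == n_exits

    def test_negative_lag_rejected(self):
        with pytest.raises(fp.ConfigurationError):
            fp.derive_daily_counts([], season_days=5, lag=-1.0)

    def test_noise_preserves_nonnegativity_and_determinism(self):
        fish = self._fish(np.linspace(1, 100, 40))
        c1 = fp.derive_daily_counts(fish, season_days=10, noise=0.5, rng=3)
        c2 = fp.derive_daily_counts(fish, season_days=10, noise=0.5, rng=3)
        arr = c1[("TD", "chinook")]
        assert np.array_equal(arr, c2[("TD", "chinook")])
        assert np.all(arr >= 0)
        assert np.all(arr == np.round(arr))


class TestGeneratorScaling:
    def test_matches_series_moments(self):
        truth = _basic_truth()
        env = fp.generate_environment(truth)
        rec = fp.generator_scaling(env, "TD", "chinook", ["temperature", "count"])
        assert rec.center["temperature"] == pytest.approx(env.temperature.mean())
        assert rec.scale["temperature"] == pytest.approx(env.temperature.std())
        key = ("TD", "chinook")
        assert rec.center["count"] == pytest.approx(env.daily_count[key].mean())
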