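"""Shared builders for synthetic worlds and hand-made risk-set data."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import fishpass as fp
from fishpass.survival import GROUP_COLUMNS, RiskSetData, build_simulation_template


def make_risk_data(
    durations,
    event,
    X,
    covariates,
    start=None,
) -> RiskSetData:
    """One-interval-per-subject risk sets with constant covariates."""
    durations = np.asarray(durations, dtype=float)
    n = durations.size
    X = np.asarray(X, dtype=float).reshape(n, -1)
    groups = pd.DataFrame(
        {
            "fish_id": [f"S{i}" for i in range(n)],
            "species": "chinook",
            "run": "none",
            "dam": "TD",
            "fishway": "main",
            "entry_hour": 0.0,
        },
        columns=GROUP_COLUMNS,
    )
    return RiskSetData(
        subject=np.arange(n),
        start=np.zeros(n) if start is None else np.asarray(start, dtype=float),
        stop=durations,
        event=np.asarray(event, dtype=bool),
        X=X,
        covariates=list(covariates),
        groups=groups,
    )


def null_world(rep: int, n_fish: float = 140.0, season_days: int = 40):
    """A world with no density effect but counts *derived from* its own
    passage events (lagged, overdispersed): the reverse-causality setup."""
    truth = fp.SimulationTruth(
        seed=100 + rep,
        season_days=season_days,
        cohorts=[
            fp.CohortSpec(
                arrival_total=n_fish, arrival_peak_day=14.0, arrival_sd_days=4.0
            )
        ],
        beta_find={"temperature": 0.4, "diel": 1.2},
        density_mode="none",
        count_lag=6.0,
        count_noise=0.15,
    )
    env = fp.generate_environment(truth)
    cohort = fp.generate_cohort(truth, env, rng=np.random.default_rng(1000 + rep))
    counts = fp.derive_daily_counts(
        cohort,
        season_days=season_days,
        lag=truth.count_lag,
        noise=truth.count_noise,
        rng=2000 + rep,
    )
    env = env.with_counts(counts)
    names = ("temperature", "diel", "count")
    raw = fp.build_counting_process(cohort, env, "finding", names)
    data, record = fp.standardize(raw)
    template = build_simulation_template(
        cohort, env, "finding", names, scaling=record
    )
    return data, template


def series_world(
    rep: int,
    n_fish: float = 800.0,
    beta_count: float = 0.5,
    season_days: int = 50,
):
    """A world whose hazard is driven by an exogenous daily count series the
    analysis can observe directly; returns the generating count coefficient
    converted to the analysis covariate scale."""
    truth = fp.SimulationTruth(
        seed=50 + rep,
        season_days=season_days,
        cohorts=[fp.CohortSpec(arrival_total=n_fish)],
        beta_find={"temperature": 0.3, "count": beta_count},
        density_mode="series",
        fixed_arrivals=True,
        count_series_noise=0.5,
    )
    env = fp.generate_environment(truth)
    cohort = fp.generate_cohort(truth, env, rng=np.random.default_rng(500 + rep))
    names = ("temperature", "count")
    raw = fp.build_counting_process(cohort, env, "finding", names)
    data, record = fp.standardize(raw)
    template = build_simulation_template(cohort, env, "finding", names, scaling=record)
    gen = fp.generator_scaling(env, "TD", "chinook", ["temperature", "count"])
    beta_analysis = beta_count / gen.scale["count"] * record.scale["count"]
    return data, template, beta_analysis


def full_world(rep: int, chinook_density: float = 0.0, season_days: int = 50):
    """Two species x two dams with runs and fishways, mirroring the paper's
    split scheme; optionally a Chinook-only density (count) effect on the
    finding and commit processes."""
    chin_find = {"temperature": 0.4, "diel": 1.3, "count": chinook_density}
    sock_find = {"temperature": 0.4, "diel": 1.3}
    chin_commit = {
        "intercept": fp.DEFAULT_COMMIT_INTERCEPT,
        "temperature": -0.3,
        "count": 0.8 * (1.0 if chinook_density else 0.0),
    }
    sock_commit = {"intercept": fp.DEFAULT_COMMIT_INTERCEPT, "temperature": -0.3}
    # arrivals well inside the season so no timestamps hit the horizon
    # (season-edge truncation would otherwise censor non-committers
    # informatively)
    timing = dict(arrival_peak_day=22.0, arrival_sd_days=5.0)
    cohorts = []
    for dam in ("JD", "TD"):
        for run in ("spring", "summer"):
            cohorts.append(
                fp.CohortSpec(
                    species="chinook", dam=dam, run=run, arrival_total=140.0,
                    beta_find=chin_find, commit_coeffs=chin_commit, **timing,
                )
            )
    cohorts.append(
        fp.CohortSpec(
            species="sockeye", dam="JD", arrival_total=170.0,
            beta_find=sock_find, commit_coeffs=sock_commit, **timing,
        )
    )
    cohorts.append(
        fp.CohortSpec(
            species="sockeye", dam="TD", arrival_total=170.0,
            fishways=("east", "north"), fishway_probs=(0.92, 0.08),
            beta_find=sock_find, commit_coeffs=sock_commit, **timing,
        )
    )
    truth = fp.SimulationTruth(
        seed=10_000 + rep,
        season_days=season_days,
        cohorts=cohorts,
        density_mode="series",
        count_series_noise=0.5,
        fishway_baseline=0.4,
    )
    env = fp.generate_environment(truth)
    cohort = fp.generate_cohort(truth, env, rng=np.random.default_rng(20_000 + rep))
    return truth, env, cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)
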