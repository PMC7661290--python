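"""End-to-end orchestration: model splitting, fitting, bootstrap inference
and scenario simulation, driven by a single configuration object.

Model "splitting" assigns disjoint cohorts (by dam / species / run /
fishway) to structurally identical models; cohorts below a minimum size
are dropped with a logged notice.  Each model runs in isolation — a
failure in one is recorded and does not stop the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import bootstrap as bs
from . import scenario as sc
from .commit import build_commit_table, fit_logistic, standardize_commit
from .errors import ConfigurationError, FishpassError
from .records import CovariateSeries, FishRecord
from .survival import (
    breslow_baseline,
    build_counting_process,
    build_simulation_template,
    fit_ph,
    standardize,
)

log = logging.getLogger("fishpass")

PROCESSES = ("finding", "fishway", "commit")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """One model family member: subset filters plus covariate structure."""

    name: str
    process: str
    species: str
    dam: str | None = None
    run: str | None = None
    fishway: str | None = None
    covariates: list[str] = field(
        default_factory=lambda: ["temperature", "diel", "count"]
    )
    null_candidates: list[list[str]] = field(
        default_factory=lambda: [["temperature", "diel"]]
    )
    count_threshold: float | None = None
    scenario_factors: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.process not in PROCESSES:
            raise ConfigurationError(f"unknown process {self.process!r}")
        full = set(self.covariates)
        if "count" not in full:
            raise ConfigurationError(
                f"model {self.name}: full covariate set must contain 'count'"
            )
        union: set[str] = set()
        for cand in self.null_candidates:
            union |= set(cand)
        if not union <= full - {"count"}:
            raise ConfigurationError(
                f"model {self.name}: null candidates must draw from the full "
                "covariate set minus the count covariate"
            )

    @property
    def subset_label(self) -> str:
        parts = [p for p in (self.run, self.fishway) if p]
        return " ".join(parts) if parts else "-"

    def matches(self, f: FishRecord) -> bool:
        if f.species != self.species:
            return False
        if self.dam is not None and f.dam != self.dam:
            return False
        if self.run is not None and f.run != self.run:
            return False
        if self.fishway is not None and f.fishway != self.fishway:
            return False
        return True


@dataclass
class AnalysisConfig:
    models: list[ModelConfig]
    min_cohort_size: int = 100
    B_null: int = 2000
    B_ci: int = 2000
    ci_level: float = 0.95
    seed: int = 0
    scenario_n_rep: int = 192
    ties: str = "breslow"

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        models = [ModelConfig(**m) for m in d.get("models", [])]
        rest = {k: v for k, v in d.items() if k != "models"}
        return cls(models=models, **rest)

    def to_dict(self) -> dict:
        return asdict(self)


def default_split_config(**overrides) -> AnalysisConfig:
    """The 13-model layout: finding and fishway PH models split by dam
    (fishway models further split by Chinook run and, for sockeye at TD,
    by specific fishway), commit models pooled across dams."""
    ph_cov = ["temperature", "diel", "count"]
    ph_null = [["temperature", "diel"], ["temperature"], ["diel"]]
    commit_cov = ["temperature", "count"]
    commit_null = [["temperature"], []]
    models = []
    for dam in ("JD", "TD"):
        for species in ("chinook", "sockeye"):
            models.append(
                ModelConfig(
                    name=f"{species}-find-{dam}",
                    process="finding",
                    species=species,
                    dam=dam,
                    covariates=list(ph_cov),
                    null_candidates=[list(c) for c in ph_null],
                )
            )
    for species in ("chinook", "sockeye"):
        models.append(
            ModelConfig(
                name=f"{species}-commit",
                process="commit",
                species=species,
                covariates=list(commit_cov),
                null_candidates=[list(c) for c in commit_null],
            )
        )
    for dam in ("JD", "TD"):
        for run in ("spring", "summer"):
            models.append(
                ModelConfig(
                    name=f"chinook-fishway-{dam}-{run}",
                    process="fishway",
                    species="chinook",
                    dam=dam,
                    run=run,
                    covariates=list(ph_cov),
                    null_candidates=[list(c) for c in ph_null],
                )
            )
    models.append(
        ModelConfig(
            name="sockeye-fishway-JD",
            process="fishway",
            species="sockeye",
            dam="JD",
            covariates=list(ph_cov),
            null_candidates=[list(c) for c in ph_null],
        )
    )
    for fishway in ("east", "north"):
        models.append(
            ModelConfig(
                name=f"sockeye-fishway-TD-{fishway}",
                process="fishway",
                species="sockeye",
                dam="TD",
                fishway=fishway,
                covariates=list(ph_cov),
                null_candidates=[list(c) for c in ph_null],
            )
        )
    return AnalysisConfig(models=models, **overrides)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def _stage_complete(f: FishRecord, process: str) -> bool:
    if process == "commit":
        return (
            f.t_first_fishway_entry is not None and f.t_last_fishway_entry is not None
        )
    return f.stage_window("finding" if process == "finding" else "fishway") is not None


def split_models(
    fish: list[FishRecord], config: AnalysisConfig
) -> tuple[dict[str, list[FishRecord]], dict[str, str]]:
    """Assign fish to model cohorts; returns (cohorts, dropped notices).

    Two models of the same family (process + species) must not claim the
    same fish; cohorts smaller than ``min_cohort_size`` (counting fish
    with the stage timestamps present) are dropped with a notice.
    """
    cohorts: dict[str, list[FishRecord]] = {}
    claimed: dict[tuple[str, str, str], str] = {}
    for m in config.models:
        members = [f for f in fish if m.matches(f)]
        for f in members:
            key = (m.process, m.species, f.fish_id)
            if key in claimed:
                raise ConfigurationError(
                    f"fish {f.fish_id} claimed by both {claimed[key]!r} and "
                    f"{m.name!r}: overlapping subset filters"
                )
            claimed[key] = m.name
        cohorts[m.name] = members

    dropped: dict[str, str] = {}
    for m in config.models:
        usable = sum(_stage_complete(f, m.process) for f in cohorts[m.name])
        if usable < config.min_cohort_size:
            dropped[m.name] = (
                f"dropped: {usable} usable fish < minimum {config.min_cohort_size}"
            )
            log.info("model %s %s", m.name, dropped[m.name])
            del cohorts[m.name]
    return cohorts, dropped


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class ModelResult:
    name: str
    process: str
    species: str
    dam: str | None
    subset: str
    n: int
    p_value: float | None = None
    ci: tuple[float, float] | None = None
    observed_coefficient: float | None = None
    null_covariates: list[str] | None = None
    coefficients: dict | None = None
    n_failures: int = 0
    unreliable: bool = False
    exclusions: dict = field(default_factory=dict)
    scenarios: list[dict] = field(default_factory=list)
    error: str | None = None
    elapsed_s: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci"] = None if self.ci is None else list(self.ci)
        return d


@dataclass
class AnalysisReport:
    results: list[ModelResult]
    dropped: dict[str, str]
    seed: int
    n_tests: int
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "results": [r.to_dict() for r in self.results],
            "dropped": dict(self.dropped),
            "seed": self.seed,
            "n_tests": self.n_tests,
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisReport":
        results = []
        for r in d["results"]:
            r = dict(r)
            if r.get("ci") is not None:
                r["ci"] = tuple(r["ci"])
            results.append(ModelResult(**r))
        return cls(
            results=results,
            dropped=dict(d["dropped"]),
            seed=d["seed"],
            n_tests=d["n_tests"],
            provenance=dict(d.get("provenance", {})),
        )

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "species": r.species,
                    "process": r.process,
                    "dam": r.dam or "-",
                    "subset": r.subset,
                    "p_value": r.p_value,
                    "ci_low": None if r.ci is None else r.ci[0],
                    "ci_high": None if r.ci is None else r.ci[1],
                    "sample_size": r.n,
                    "error": r.error,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


def _model_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0])


def run_model(
    m: ModelConfig,
    cohort: list[FishRecord],
    env: CovariateSeries,
    config: AnalysisConfig,
    seed: int,
) -> ModelResult:
    """Fit one model end to end: build, standardize, AICc-select the null,
    bootstrap test + CI, scenarios."""
    t0 = time.perf_counter()
    base_cov = [c for c in m.covariates]
    if m.process == "commit":
        table = build_commit_table(
            cohort, env, covariates=tuple(base_cov), count_threshold=m.count_threshold
        )
        data, _ = standardize_commit(table)
        n = data.n
        exclusions = data.exclusions
        template = None
    else:
        raw = build_counting_process(
            cohort,
            env,
            stage=m.process,
            covariates=tuple(base_cov),
            count_threshold=m.count_threshold,
        )
        data, scaling_record = standardize(raw)
        n = data.n_subjects
        exclusions = data.exclusions
        template = build_simulation_template(
            cohort,
            env,
            stage=m.process,
            covariates=tuple(base_cov),
            count_threshold=m.count_threshold,
            scaling=scaling_record,
        )

    full_set = list(data.covariates)
    null_candidates = [list(c) for c in m.null_candidates]
    if m.count_threshold is not None:
        # threshold indicator is part of the null model
        null_candidates = [c + ["count_thresh"] for c in null_candidates]
    null_fit, null_set = bs.select_null_model(data, null_candidates)

    seed_test = _model_seed(seed, 0)
    seed_ci = _model_seed(seed, 1)
    kwargs = (
        {"ties": config.ties, "template": template} if m.process != "commit" else {}
    )
    test = bs.null_bootstrap_test(
        data,
        null_set,
        full_set,
        B=config.B_null,
        seed=seed_test,
        null_fit=null_fit,
        **kwargs,
    )
    ci = bs.full_model_bootstrap_ci(
        data,
        full_set,
        B=config.B_ci,
        level=config.ci_level,
        seed=seed_ci,
        **kwargs,
    )

    scenarios: list[dict] = []
    if m.scenario_factors:
        if m.process == "commit":
            full_fit = fit_logistic(data, full_set)
            for j, factor in enumerate(m.scenario_factors):
                res = sc.run_commit_scenario(
                    full_fit,
                    data,
                    factor,
                    n_rep=config.scenario_n_rep,
                    seed=_model_seed(seed, 10 + j),
                )
                scenarios.append(res.to_dict())
        else:
            full_fit = fit_ph(data, full_set, ties=config.ties)
            baseline = breslow_baseline(full_fit, data)
            for j, factor in enumerate(m.scenario_factors):
                res = sc.run_density_scenario(
                    full_fit,
                    baseline,
                    template,
                    factor,
                    n_rep=config.scenario_n_rep,
                    seed=_model_seed(seed, 10 + j),
                )
                scenarios.append(res.to_dict())

    full_fit_obs = _fit_full(data, full_set, m, config)
    coeffs = {
        "names": full_fit_obs.covariates,
        "beta_standardized": np.asarray(full_fit_obs.beta).tolist(),
        "se": np.asarray(full_fit_obs.se).tolist(),
        "null_aicc": null_fit.aicc,
    }
    return ModelResult(
        name=m.name,
        process=m.process,
        species=m.species,
        dam=m.dam,
        subset=m.subset_label,
        n=n,
        p_value=test.p_value,
        ci=ci.ci,
        observed_coefficient=test.observed_coefficient,
        null_covariates=null_set,
        coefficients=coeffs,
        n_failures=test.n_failures + ci.n_failures,
        unreliable=test.unreliable or ci.unreliable,
        exclusions=exclusions,
        scenarios=scenarios,
        elapsed_s=round(time.perf_counter() - t0, 3),
    )


def _fit_full(data, full_set, m: ModelConfig, config: AnalysisConfig):
    if m.process == "commit":
        return fit_logistic(data, full_set)
    return fit_ph(data, full_set, ties=config.ties)


def run_pipeline(
    config: AnalysisConfig, fish: list[FishRecord], env: CovariateSeries
) -> AnalysisReport:
    """Run every configured model; failures are isolated per model."""
    cohorts, dropped = split_models(fish, config)
    results: list[ModelResult] = []
    for i, m in enumerate(config.models):
        if m.name not in cohorts:
            continue
        seed = _model_seed(config.seed, 1000 + i)
        t0 = time.perf_counter()
        try:
            res = run_model(m, cohorts[m.name], env, config, seed)
        except FishpassError as exc:
            log.warning("model %s failed: %s", m.name, exc)
            res = ModelResult(
                name=m.name,
                process=m.process,
                species=m.species,
                dam=m.dam,
                subset=m.subset_label,
                n=len(cohorts[m.name]),
                error=str(exc),
                elapsed_s=round(time.perf_counter() - t0, 3),
            )
        log.info("model %s finished in %.2fs", m.name, time.perf_counter() - t0)
        results.append(res)
    n_tests = sum(1 for r in results if r.p_value is not None)
    from . import __version__

    config_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]
    return AnalysisReport(
        results=results,
        dropped=dropped,
        seed=config.seed,
        n_tests=n_tests,
        provenance={
            "config_hash": config_hash,
            "seed": config.seed,
            "version": __version__,
        },
    )
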