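"""Parametric-bootstrap inference for the density (count) coefficient.

The test simulates full datasets from a fitted *null* model (one with no
count covariate), keeps the observed count covariate series attached
unchanged, refits the full model to each simulated dataset, and uses the
refitted count coefficients as the null distribution.  Because the null
model contains no count-to-hazard causal link, the resulting p-values
remain valid even when the observed counts were produced by the passage
process itself (reverse causality).

Confidence intervals come from a second bootstrap that simulates from the
*full* fitted model and takes percentile bounds of the refitted count
coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .commit import CommitTable, LogisticFit, fit_logistic
from .errors import ConfigurationError, ConvergenceError, DataError
from .survival import (
    PHFit,
    RiskSetData,
    breslow_baseline,
    fit_ph,
    simulate_event_times,
)

MAX_FAILURE_FRACTION = 0.05


def two_sided_p(observed: float, null_draws: np.ndarray) -> float:
    """Add-one two-sided p-value: (1 + #{|b*| >= |b_obs|}) / (B + 1)."""
    draws = np.asarray(null_draws, dtype=float)
    return float((1.0 + np.sum(np.abs(draws) >= abs(observed))) / (draws.size + 1.0))


def percentile_interval(draws: np.ndarray, level: float) -> tuple[float, float]:
    """Order-statistic percentile interval.

    With B draws and level 1 - 2a the bounds are the k-th and (B+1-k)-th
    order statistics, k = floor((B + 1) * a); e.g. B = 1999, level 0.95
    gives the 50th and 1950th.
    """
    if not 0 < level < 1:
        raise ConfigurationError("level must be in (0, 1)")
    draws = np.sort(np.asarray(draws, dtype=float))
    B = draws.size
    alpha = (1.0 - level) / 2.0
    k = int(np.floor((B + 1) * alpha))
    k = max(k, 1)
    return float(draws[k - 1]), float(draws[B - k])


@dataclass
class BootstrapResult:
    """Null-distribution test and/or CI for one model's count coefficient."""

    observed_coefficient: float
    null_draws: np.ndarray | None
    p_value: float | None
    ci_draws: np.ndarray | None
    ci: tuple[float, float] | None
    ci_level: float | None
    B_null: int
    B_ci: int
    seed: int
    n_failures: int
    unreliable: bool = False

    def to_dict(self, include_draws: bool = True) -> dict:
        d = {
            "observed_coefficient": self.observed_coefficient,
            "p_value": self.p_value,
            "ci": None if self.ci is None else list(self.ci),
            "ci_level": self.ci_level,
            "B_null": self.B_null,
            "B_ci": self.B_ci,
            "seed": self.seed,
            "n_failures": self.n_failures,
            "unreliable": self.unreliable,
        }
        if include_draws:
            d["null_draws"] = (
                None if self.null_draws is None else np.asarray(self.null_draws).tolist()
            )
            d["ci_draws"] = (
                None if self.ci_draws is None else np.asarray(self.ci_draws).tolist()
            )
        return d


# ---------------------------------------------------------------------------
# null-model selection
# ---------------------------------------------------------------------------


def select_null_model(
    data,
    candidate_covariate_sets: list[list[str]],
    count_name: str = "count",
    **fit_kwargs,
):
    """AICc-minimal candidate; ties broken toward fewer covariates.

    Candidates must not contain the count covariate (nullity).
    Returns (fit, covariate_set).
    """
    if not candidate_covariate_sets:
        raise ConfigurationError("need at least one candidate covariate set")
    for cand in candidate_covariate_sets:
        if count_name in cand:
            raise ConfigurationError(
                f"null candidate {cand} contains the count covariate "
                f"{count_name!r} (nullity violated)"
            )
    # stable sort by size so AICc ties resolve toward fewer covariates
    ranked = sorted(candidate_covariate_sets, key=len)
    best = None
    for cand in ranked:
        fit = _dispatch_fit(data, list(cand), **fit_kwargs)
        if best is None or fit.aicc < best[0].aicc - 1e-12:
            best = (fit, list(cand))
    return best


def _dispatch_fit(data, covariate_set, init=None, **kwargs):
    if isinstance(data, RiskSetData):
        return fit_ph(data, covariate_set, init=init, **kwargs)
    if isinstance(data, CommitTable):
        return fit_logistic(data, covariate_set, **kwargs)
    raise ConfigurationError(f"cannot fit data of type {type(data).__name__}")


# ---------------------------------------------------------------------------
# simulation of one dataset from a fitted model
# ---------------------------------------------------------------------------


def _simulate_ph_dataset(
    fit: PHFit, baseline, template: RiskSetData, rng: np.random.Generator
) -> RiskSetData:
    sim = simulate_event_times(fit, baseline, template, seed=rng)
    return template.with_event_times(sim.times, sim.resolved)


def _simulate_commit_outcomes(
    fit: LogisticFit, table: CommitTable, rng: np.random.Generator
) -> CommitTable:
    idx = [table.covariates.index(n) for n in fit.covariates]
    p = fit.predict_proba(table.X[:, idx])
    table2 = CommitTable(
        y=(rng.random(table.n) < p).astype(float),
        X=table.X,
        covariates=list(table.covariates),
        groups=table.groups,
        scaling=table.scaling,
        raw_X=table.raw_X,
        count_threshold=table.count_threshold,
        exclusions=dict(table.exclusions),
    )
    return table2


# ---------------------------------------------------------------------------
# the null-distribution test
# ---------------------------------------------------------------------------


def null_bootstrap_test(
    data,
    null_covariates: list[str],
    full_covariates: list[str],
    B: int = 2000,
    seed: int = 0,
    count_name: str = "count",
    null_fit=None,
    observed_fit=None,
    ties: str = "breslow",
    template: RiskSetData | None = None,
) -> BootstrapResult:
    """Parametric-bootstrap p-value for the count coefficient.

    Simulated datasets come from the fitted null model (event times for PH
    data; Bernoulli outcomes for commit tables) with the observed count
    covariate held at its observed values, so the null distribution
    contains no count-to-outcome causal link.  For PH data a ``template``
    with extended follow-up (see ``build_simulation_template``) avoids
    censoring simulated event times at each fish's observed duration; it
    defaults to the observed risk sets.
    """
    if B < 99:
        raise ConfigurationError("B must be at least 99")
    if count_name in null_covariates:
        raise ConfigurationError("null model must not contain the count covariate")
    if count_name not in full_covariates:
        raise ConfigurationError("full model must contain the count covariate")
    rng = np.random.default_rng(seed)
    is_ph = isinstance(data, RiskSetData)
    kwargs = {"ties": ties} if is_ph else {}

    if observed_fit is None:
        observed_fit = _dispatch_fit(data, list(full_covariates), **kwargs)
    observed = observed_fit.coefficient(count_name)
    if null_fit is None:
        null_fit = _dispatch_fit(data, list(null_covariates), **kwargs)

    if is_ph:
        baseline = breslow_baseline(null_fit, data)
        if template is None:
            template = data
    draws = np.empty(B)
    failures = 0
    warm = observed_fit.beta if is_ph else None
    for b in range(B):
        try:
            if is_ph:
                sim = _simulate_ph_dataset(null_fit, baseline, template, rng)
                refit = fit_ph(sim, list(full_covariates), init=warm, ties=ties)
            else:
                sim = _simulate_commit_outcomes(null_fit, data, rng)
                refit = fit_logistic(sim, list(full_covariates))
            draws[b] = refit.coefficient(count_name)
        except (ConvergenceError, DataError):
            draws[b] = np.nan
            failures += 1
    ok = draws[~np.isnan(draws)]
    if ok.size == 0:
        raise ConvergenceError("all bootstrap refits failed")
    unreliable = failures > MAX_FAILURE_FRACTION * B
    if unreliable:
        warnings.warn(
            f"{failures}/{B} bootstrap refits failed to converge; "
            "result flagged unreliable",
            stacklevel=2,
        )
    return BootstrapResult(
        observed_coefficient=observed,
        null_draws=ok,
        p_value=two_sided_p(observed, ok),
        ci_draws=None,
        ci=None,
        ci_level=None,
        B_null=B,
        B_ci=0,
        seed=seed,
        n_failures=failures,
        unreliable=unreliable,
    )


def full_model_bootstrap_ci(
    data,
    full_covariates: list[str],
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    count_name: str = "count",
    full_fit=None,
    ties: str = "breslow",
    template: RiskSetData | None = None,
) -> BootstrapResult:
    """Percentile CI for the count coefficient from the full fitted model."""
    if B < 199:
        raise ConfigurationError("B must be at least 199 for a CI")
    rng = np.random.default_rng(seed)
    is_ph = isinstance(data, RiskSetData)
    kwargs = {"ties": ties} if is_ph else {}
    if full_fit is None:
        full_fit = _dispatch_fit(data, list(full_covariates), **kwargs)
    observed = full_fit.coefficient(count_name)
    if is_ph:
        baseline = breslow_baseline(full_fit, data)
        if template is None:
            template = data
    draws = np.empty(B)
    failures = 0
    for b in range(B):
        try:
            if is_ph:
                sim = _simulate_ph_dataset(full_fit, baseline, template, rng)
                refit = fit_ph(sim, list(full_covariates), init=full_fit.beta, ties=ties)
            else:
                sim = _simulate_commit_outcomes(full_fit, data, rng)
                refit = fit_logistic(sim, list(full_covariates))
            draws[b] = refit.coefficient(count_name)
        except (ConvergenceError, DataError):
            draws[b] = np.nan
            failures += 1
    ok = draws[~np.isnan(draws)]
    if ok.size == 0:
        raise ConvergenceError("all bootstrap refits failed")
    unreliable = failures > MAX_FAILURE_FRACTION * B
    if unreliable:
        warnings.warn(
            f"{failures}/{B} bootstrap refits failed to converge; "
            "result flagged unreliable",
            stacklevel=2,
        )
    return BootstrapResult(
        observed_coefficient=observed,
        null_draws=None,
        p_value=None,
        ci_draws=ok,
        ci=percentile_interval(ok, level),
        ci_level=level,
        B_null=0,
        B_ci=B,
        seed=seed,
        n_failures=failures,
        unreliable=unreliable,
    )
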