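"""Synthetic telemetry world with known ground truth.

Generates environmental covariate series, per-fish stage histories driven
by proportional-hazards models with time-varying covariates, Bernoulli
first-attempt commit outcomes, and observer-style daily counts derived
*from* the simulated passage events (optionally lagged and overdispersed).
The density covariate driving the hazard is configurable:

* ``none``   - no density effect (null worlds for calibration studies);
* ``series`` - an exogenous daily count series drives the hazard, and the
  analysis can observe the same series (parameter-recovery worlds);
* ``latent`` - the instantaneous number of fish present in the tailrace
  drives the hazard while the analysis only ever sees derived daily
  counts, separating the causal variable from its proxy.

Timestamps that would land beyond the season horizon are recorded as
missing (the fish was "never observed" completing that stage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigurationError, DataError
from .hazards import PiecewiseConstantHazard, draw_event_times
from .records import HOURS_PER_DAY, CovariateSeries, FishRecord
from .scaling import ScalingRecord

#: commit intercept giving probability 0.43 at covariate zero
DEFAULT_COMMIT_INTERCEPT = math.log(0.43 / 0.57)

ENV_NAMES = ("temperature", "spill", "diel", "count")


def _as_hazard(spec) -> PiecewiseConstantHazard:
    if isinstance(spec, PiecewiseConstantHazard):
        return spec
    if isinstance(spec, (int, float)):
        return PiecewiseConstantHazard.constant(float(spec))
    if isinstance(spec, dict):
        return PiecewiseConstantHazard(
            np.asarray(spec["breaks"], dtype=float),
            np.asarray(spec["rates"], dtype=float),
        )
    raise ConfigurationError(f"cannot interpret hazard spec {spec!r}")


@dataclass
class CohortSpec:
    """One species/run/dam cohort of arriving fish."""

    species: str = "chinook"
    dam: str = "TD"
    run: str = "none"
    fishways: tuple[str, ...] = ("main",)
    fishway_probs: tuple[float, ...] | None = None
    arrival_total: float = 200.0
    arrival_peak_day: float | None = None
    arrival_sd_days: float | None = None
    beta_find: dict[str, float] | None = None
    beta_fishway: dict[str, float] | None = None
    commit_coeffs: dict[str, float] | None = None


@dataclass
class SimulationTruth:
    """Ground-truth parameters for one synthetic world.

    Hazard coefficients are on the generator-standardized scale (daily
    covariate series z-scored over the season); ``generator_scaling``
    exposes the centering/scaling used so estimates can be converted.
    """

    seed: int = 0
    season_days: int = 60
    cohorts: list[CohortSpec] = field(default_factory=lambda: [CohortSpec()])
    beta_find: dict[str, float] = field(default_factory=dict)
    beta_fishway: dict[str, float] = field(default_factory=dict)
    commit_coeffs: dict[str, float] = field(
        default_factory=lambda: {"intercept": DEFAULT_COMMIT_INTERCEPT}
    )
    find_baseline: object = 0.08
    fishway_baseline: object = 0.5
    density_mode: str = "none"
    count_lag: float = 0.0
    count_noise: float = 0.0
    reattempt_mean_gap: float = 12.0
    dropout: float = 0.0
    fixed_arrivals: bool = False
    max_followup_hours: float = 192.0
    fishway_followup_hours: float = 96.0
    # environment
    temp_mean: float = 16.0
    temp_amplitude: float = 3.0
    temp_period_days: float = 120.0
    temp_phase_days: float = 0.0
    temp_ar_sd: float = 0.8
    temp_ar_phi: float = 0.7
    spill_mean: float = 100.0
    spill_amplitude: float = 40.0
    spill_sd: float = 10.0
    day_window: tuple[float, float] = (6.0, 18.0)
    # exogenous count series (density_mode == "series", or plumbing default)
    count_series_peak: float = 2000.0
    count_series_sd_days: float | None = None
    count_series_noise: float = 0.25
    # latent-density scaling (density_mode == "latent")
    latent_center: float = 10.0
    latent_scale: float = 5.0

    def __post_init__(self) -> None:
        if self.season_days <= 0:
            raise ConfigurationError("season length must be positive")
        if self.density_mode not in ("none", "series", "latent"):
            raise ConfigurationError(f"unknown density_mode {self.density_mode!r}")
        if self.count_lag < 0:
            raise ConfigurationError("count_lag must be >= 0")
        if self.count_noise < 0:
            raise ConfigurationError("count_noise must be >= 0")
        self.find_baseline = _as_hazard(self.find_baseline)
        self.fishway_baseline = _as_hazard(self.fishway_baseline)
        for cohort in self.cohorts:
            if cohort.arrival_total < 0:
                raise ConfigurationError("arrival_total must be >= 0")

    def arrival_intensity(self, cohort: CohortSpec) -> np.ndarray:
        """Expected arrivals per day (Gaussian run-timing curve)."""
        peak = (
            cohort.arrival_peak_day
            if cohort.arrival_peak_day is not None
            else self.season_days / 2.0
        )
        sd = (
            cohort.arrival_sd_days
            if cohort.arrival_sd_days is not None
            else self.season_days / 8.0
        )
        days = np.arange(self.season_days)
        shape = np.exp(-0.5 * ((days + 0.5 - peak) / sd) ** 2)
        total = shape.sum()
        if total <= 0:
            raise ConfigurationError("degenerate arrival intensity")
        return cohort.arrival_total * shape / total

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("find_baseline", "fishway_baseline"):
            h = getattr(self, key)
            d[key] = {"breaks": h.breaks.tolist(), "rates": h.rates.tolist()}
        return d


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


def generate_environment(truth: SimulationTruth) -> CovariateSeries:
    """Daily temperature (sinusoid + AR(1) noise), spill, diel window and an
    exogenous daily count series per (dam, species); deterministic given
    ``truth.seed``."""
    rng = np.random.default_rng(truth.seed)
    days = np.arange(truth.season_days)

    temp = truth.temp_mean + truth.temp_amplitude * np.sin(
        2.0 * np.pi * (days - truth.temp_phase_days) / truth.temp_period_days
    )
    if truth.temp_ar_sd > 0:
        noise = np.empty(truth.season_days)
        eps = rng.normal(0.0, truth.temp_ar_sd, size=truth.season_days)
        prev = 0.0
        for d in range(truth.season_days):
            prev = truth.temp_ar_phi * prev + eps[d]
            noise[d] = prev
        temp = temp + noise

    spill = truth.spill_mean + truth.spill_amplitude * np.sin(
        2.0 * np.pi * days / max(truth.season_days, 1)
    )
    if truth.spill_sd > 0:
        spill = spill + rng.normal(0.0, truth.spill_sd, size=truth.season_days)
    spill = np.maximum(spill, 0.0)

    sd = (
        truth.count_series_sd_days
        if truth.count_series_sd_days is not None
        else truth.season_days / 6.0
    )
    counts: dict[tuple[str, str], np.ndarray] = {}
    for cohort in truth.cohorts:
        key = (cohort.dam, cohort.species)
        if key in counts:
            continue
        shape = np.exp(-0.5 * ((days + 0.5 - truth.season_days / 2.0) / sd) ** 2)
        series = truth.count_series_peak * shape
        if truth.count_series_noise > 0:
            series = series * rng.lognormal(
                mean=-0.5 * truth.count_series_noise**2,
                sigma=truth.count_series_noise,
                size=truth.season_days,
            )
        counts[key] = np.round(series)

    return CovariateSeries(
        season_days=truth.season_days,
        temperature=temp,
        spill=spill,
        daily_count=counts,
        day_window=truth.day_window,
    )


def generator_scaling(
    env: CovariateSeries, dam: str, species: str, names: list[str]
) -> ScalingRecord:
    """The z-scoring the generator applies to each covariate (population
    moments over season days; diel passes through)."""
    center: dict[str, float] = {}
    scale: dict[str, float] = {}
    binary = set()
    for name in names:
        if name == "diel":
            center[name], scale[name] = 0.0, 1.0
            binary.add(name)
            continue
        if name == "temperature":
            series = env.temperature
        elif name == "spill":
            series = env.spill
        elif name == "count":
            series = env.daily_count[(dam, species)]
        else:
            raise ConfigurationError(f"unknown covariate {name!r}")
        mu = float(series.mean())
        sd = float(series.std())
        if sd <= 0:
            raise DataError(f"covariate {name} is constant over the season")
        center[name], scale[name] = mu, sd
    return ScalingRecord(center=center, scale=scale, binary=frozenset(binary))


# ---------------------------------------------------------------------------
# hazard paths
# ---------------------------------------------------------------------------


class _LogHRPath:
    """Step function of the generator's log hazard ratio in calendar time.

    Breakpoints are the union of day boundaries and the diel window edges;
    lookups past the season hold the final day's values.
    """

    def __init__(
        self,
        truth: SimulationTruth,
        env: CovariateSeries,
        beta: dict[str, float],
        dam: str,
        species: str,
    ):
        horizon_days = truth.season_days + 14
        lo, hi = env.day_window
        d = np.arange(horizon_days)
        pts = np.unique(
            np.concatenate(
                [d * HOURS_PER_DAY, d * HOURS_PER_DAY + lo, d * HOURS_PER_DAY + hi]
            )
        )
        self.breaks = pts
        day_idx = np.minimum(
            (pts / HOURS_PER_DAY).astype(int), env.season_days - 1
        )
        scaling = generator_scaling(
            env, dam, species, [n for n in beta if n not in ("diel", "density")]
        )
        loghr = np.zeros(pts.size)
        for name, b in beta.items():
            if b == 0.0:
                continue
            if name == "diel":
                tod = np.mod(pts, HOURS_PER_DAY)
                loghr += b * ((tod >= lo) & (tod < hi)).astype(float)
            elif name == "density":
                continue  # latent density handled by the sequential simulator
            else:
                if name == "temperature":
                    series = env.temperature
                elif name == "spill":
                    series = env.spill
                elif name == "count":
                    series = env.daily_count[(dam, species)]
                else:
                    raise ConfigurationError(f"unknown covariate {name!r}")
                z = (series[day_idx] - scaling.center[name]) / scaling.scale[name]
                loghr += b * z
        self.values = loghr

    def segments(self, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, stops, loghr) of the step function restricted to (t0, t1)."""
        inner = self.breaks[(self.breaks > t0) & (self.breaks < t1)]
        edges = np.concatenate([[t0], inner, [t1]])
        idx = np.clip(
            np.searchsorted(self.breaks, edges[:-1], side="right") - 1, 0, None
        )
        return edges[:-1], edges[1:], self.values[idx]

    def value_at(self, t: float) -> float:
        idx = max(int(np.searchsorted(self.breaks, t, side="right")) - 1, 0)
        return float(self.values[idx])


def _draw_stage_times(
    baseline: PiecewiseConstantHazard,
    path: _LogHRPath,
    origins: np.ndarray,
    followup: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Event times (hours after each origin) under baseline * exp(path); NaN
    when the event does not occur within the follow-up window."""
    n = origins.size
    if n == 0:
        return np.zeros(0)
    starts, stops, loghrs, bounds, subj = [], [], [], [0], 0
    for a in origins:
        s0, s1, lh = path.segments(a, a + followup)
        starts.append(s0 - a)
        stops.append(s1 - a)
        loghrs.append(lh)
        subj += s0.size
        bounds.append(subj)
    times, resolved = draw_event_times(
        baseline,
        np.concatenate(starts),
        np.concatenate(stops),
        np.concatenate(loghrs),
        np.asarray(bounds),
        rng.exponential(size=n),
    )
    return np.where(resolved, times, np.nan)


def _latent_finding_times(
    truth: SimulationTruth,
    env: CovariateSeries,
    path: _LogHRPath,
    arrivals: np.ndarray,
    beta_density: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sequential hourly simulation where the hazard multiplier includes the
    z-scored number of fish currently searching the tailrace."""
    n = arrivals.size
    found = np.full(n, np.nan)
    active = np.zeros(n, dtype=bool)
    horizon = int(env.season_days * HOURS_PER_DAY + truth.max_followup_hours)
    baseline = truth.find_baseline
    for h in range(horizon):
        newly = (arrivals >= h) & (arrivals < h + 1)
        active |= newly
        idx = np.flatnonzero(active)
        if idx.size == 0:
            if np.all(arrivals < h):
                break
            continue
        occupancy = idx.size
        z_occ = (occupancy - truth.latent_center) / truth.latent_scale
        loghr = path.value_at(h + 0.0) + beta_density * z_occ
        t_in = np.maximum(arrivals[idx], float(h))
        exposure = (h + 1.0) - t_in
        u = t_in - arrivals[idx]  # subject time at the start of exposure
        rate = baseline.rates[
            np.clip(np.searchsorted(baseline.breaks, u, side="right") - 1, 0, None)
        ] * np.exp(loghr)
        p = -np.expm1(-rate * exposure)
        hit = rng.random(idx.size) < p
        if np.any(hit):
            sel = idx[hit]
            r = rate[hit]
            e = exposure[hit]
            # exact draw from the rate-truncated exponential within the hour
            v = rng.random(sel.size)
            dt = -np.log1p(-v * (-np.expm1(-r * e))) / r
            found[sel] = t_in[hit] + dt
            active[sel] = False
        timed_out = active & (np.maximum(arrivals, 0) + truth.max_followup_hours < h)
        active[timed_out] = False
    return found


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(
    truth: SimulationTruth,
    env: CovariateSeries,
    rng: np.random.Generator | None = None,
) -> list[FishRecord]:
    """Simulate a full cohort of fish records from the ground truth."""
    if env.season_days != truth.season_days:
        raise DataError("environment and truth must cover the same season")
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    season_hours = truth.season_days * HOURS_PER_DAY
    records: list[FishRecord] = []
    serial = 0

    for cohort in truth.cohorts:
        intensity = truth.arrival_intensity(cohort)
        if truth.fixed_arrivals:
            n = int(round(cohort.arrival_total))
            days = rng.choice(
                truth.season_days, size=n, p=intensity / intensity.sum()
            )
        else:
            per_day = rng.poisson(intensity)
            days = np.repeat(np.arange(truth.season_days), per_day)
            n = days.size
        arrivals = days * HOURS_PER_DAY + rng.uniform(0, HOURS_PER_DAY, size=n)
        arrivals.sort()

        beta_find = cohort.beta_find if cohort.beta_find is not None else truth.beta_find
        beta_fw = (
            cohort.beta_fishway
            if cohort.beta_fishway is not None
            else truth.beta_fishway
        )
        commit = (
            cohort.commit_coeffs
            if cohort.commit_coeffs is not None
            else truth.commit_coeffs
        )

        find_path = _LogHRPath(truth, env, beta_find, cohort.dam, cohort.species)
        if truth.density_mode == "latent":
            beta_density = float(beta_find.get("density", 0.0))
            find_delay = _latent_finding_times(
                truth, env, find_path, arrivals, beta_density, rng
            )
        else:
            find_delay = _draw_stage_times(
                truth.find_baseline,
                find_path,
                arrivals,
                truth.max_followup_hours,
                rng,
            )
        t_first = arrivals + find_delay  # NaN propagates for unresolved fish

        # commit decision at first fishway entry
        commit_scaling = generator_scaling(
            env,
            cohort.dam,
            cohort.species,
            [n_ for n_ in commit if n_ not in ("intercept", "diel")],
        )
        logits = np.full(n, float(commit.get("intercept", 0.0)))
        ok = np.isfinite(t_first) & (t_first < season_hours)
        day_at = np.clip(
            (np.where(ok, t_first, 0.0) / HOURS_PER_DAY).astype(int),
            0,
            env.season_days - 1,
        )
        for name, b in commit.items():
            if name == "intercept" or b == 0.0:
                continue
            if name == "diel":
                tod = np.mod(np.where(ok, t_first, 0.0), HOURS_PER_DAY)
                lo, hi = env.day_window
                logits += b * ((tod >= lo) & (tod < hi)).astype(float)
                continue
            if name == "temperature":
                series = env.temperature
            elif name == "spill":
                series = env.spill
            elif name == "count":
                series = env.daily_count[(cohort.dam, cohort.species)]
            else:
                raise ConfigurationError(f"unknown commit covariate {name!r}")
            z = (series[day_at] - commit_scaling.center[name]) / commit_scaling.scale[name]
            logits += b * z
        p_commit = 1.0 / (1.0 + np.exp(-logits))
        committed = rng.random(n) < p_commit

        gaps = np.where(
            committed, 0.0, rng.exponential(truth.reattempt_mean_gap, size=n)
        )
        t_last = t_first + gaps

        fw_path = _LogHRPath(truth, env, beta_fw, cohort.dam, cohort.species)
        origins = np.where(np.isfinite(t_last), t_last, 0.0)
        transit = _draw_stage_times(
            truth.fishway_baseline,
            fw_path,
            origins,
            truth.fishway_followup_hours,
            rng,
        )
        transit = np.where(np.isfinite(t_last), transit, np.nan)
        t_exit = t_last + transit

        if cohort.fishway_probs is not None:
            probs = np.asarray(cohort.fishway_probs, dtype=float)
            probs = probs / probs.sum()
        else:
            probs = np.full(len(cohort.fishways), 1.0 / len(cohort.fishways))
        fishway_labels = rng.choice(list(cohort.fishways), size=n, p=probs)

        for i in range(n):
            serial += 1
            ts = [arrivals[i], t_first[i], t_last[i], t_exit[i]]
            # beyond-horizon or unresolved timestamps become missing, along
            # with everything after them
            clean: list[float | None] = []
            broken = False
            for t in ts:
                if broken or not np.isfinite(t) or t >= season_hours:
                    clean.append(None)
                    broken = True
                else:
                    clean.append(float(t))
            if truth.dropout > 0:
                clean = [
                    None if rng.random() < truth.dropout else t for t in clean
                ]
            committed_flag: bool | None
            if clean[1] is not None and clean[2] is not None:
                committed_flag = clean[1] == clean[2]
            else:
                committed_flag = None
            records.append(
                FishRecord(
                    fish_id=f"F{serial:05d}",
                    species=cohort.species,
                    run=cohort.run,
                    dam=cohort.dam,
                    fishway=str(fishway_labels[i]),
                    t_tailrace_entry=clean[0],
                    t_first_fishway_entry=clean[1],
                    t_last_fishway_entry=clean[2],
                    t_fishway_exit=clean[3],
                    committed_first_attempt=committed_flag,
                )
            )
    return records


# ---------------------------------------------------------------------------
# derived observer counts
# ---------------------------------------------------------------------------


def derive_daily_counts(
    cohort: list[FishRecord],
    season_days: int,
    lag: float = 0.0,
    noise: float = 0.0,
    window_offset: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> dict[tuple[str, str], np.ndarray]:
    """Daily counts computed *from* passage events.

    A fish is counted on the day containing ``t_fishway_exit -
    window_offset + lag`` (the observation window sits below the ladder
    exit; the lag models delayed tallying).  ``noise`` is a negative-
    binomial overdispersion parameter (variance = m + noise * m^2); zero
    noise reproduces the exact tallies.  This construction is what makes
    counts a *function of* passage — the reverse-causality structure the
    bootstrap must survive.
    """
    if lag < 0:
        raise ConfigurationError("lag must be >= 0")
    if noise < 0:
        raise ConfigurationError("noise must be >= 0")
    if window_offset < 0:
        raise ConfigurationError("window_offset must be >= 0")
    rng = (
        rng
        if isinstance(rng, np.random.Generator)
        else np.random.default_rng(0 if rng is None else rng)
    )
    keys = sorted({(f.dam, f.species) for f in cohort})
    out = {key: np.zeros(season_days) for key in keys}
    for f in cohort:
        if f.t_fishway_exit is None:
            continue
        t = f.t_fishway_exit - window_offset + lag
        if not np.isfinite(t):
            raise DataError(f"fish {f.fish_id}: non-finite exit time")
        day = int(np.floor(t / HOURS_PER_DAY))
        if 0 <= day < season_days:
            out[(f.dam, f.species)][day] += 1
    if noise > 0:
        r = 1.0 / noise
        for key, series in out.items():
            m = series
            with np.errstate(divide="ignore", invalid="ignore"):
                p = r / (r + m)
            noisy = np.where(
                m > 0, rng.negative_binomial(r, np.where(m > 0, p, 1.0)), 0.0
            )
            out[key] = noisy.astype(float)
    else:
        out = {k: v.astype(float) for k, v in out.items()}
    return out
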