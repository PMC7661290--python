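"""Counting-process survival engine.

Builds (start, stop] risk-set data with piecewise-constant time-varying
covariates from per-fish stage timestamps, fits the proportional-hazards
model by Newton-Raphson on the Breslow partial likelihood, estimates the
Breslow baseline cumulative hazard, simulates event times from a fitted
model by cumulative-hazard inversion, and provides a permutation-based
proportional-hazards diagnostic.

Each subject's clock starts at its own stage entry (tailrace entry for the
finding stage; last fishway entry for the fishway stage); calendar-time
covariates are mapped onto subject time through the entry timestamp.
Intervals are half-open (start, stop] and carry the covariate value at the
interval start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConvergenceError, DataError, RankDeficiencyError
from .hazards import BaselineHazard, draw_event_times
from .records import CovariateSeries, FishRecord
from .scaling import ScalingRecord

THRESHOLD_NAME = "count_thresh"

GROUP_COLUMNS = ["fish_id", "species", "run", "dam", "fishway", "entry_hour"]


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass
class RiskSetData:
    """Counting-process intervals for one stage model.

    Rows are sorted by subject then start; each subject's intervals are
    contiguous, with the event flag (if any) on its final interval.
    ``subject`` holds contiguous integer codes 0..n_subjects-1 indexing
    rows of ``groups``.
    """

    subject: np.ndarray
    start: np.ndarray
    stop: np.ndarray
    event: np.ndarray
    X: np.ndarray
    covariates: list[str]
    groups: pd.DataFrame
    scaling: ScalingRecord | None = None
    raw_X: np.ndarray | None = None
    count_threshold: float | None = None
    exclusions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.subject = np.asarray(self.subject, dtype=int)
        self.start = np.asarray(self.start, dtype=float)
        self.stop = np.asarray(self.stop, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        self.X = np.asarray(self.X, dtype=float).reshape(len(self.start), len(self.covariates))

    # -- basic shape ----------------------------------------------------

    @property
    def n_intervals(self) -> int:
        return self.start.size

    @property
    def n_subjects(self) -> int:
        return len(self.groups)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subject_bounds(self) -> np.ndarray:
        if self.subject.size == 0:
            return np.zeros(self.n_subjects + 1, dtype=int)
        changes = np.flatnonzero(np.diff(self.subject)) + 1
        return np.concatenate([[0], changes, [self.subject.size]])

    def validate(self) -> None:
        if np.any(self.start >= self.stop):
            raise DataError("intervals must satisfy start < stop")
        if not np.all(np.isfinite(self.X)):
            raise DataError("covariates must be finite")
        if self.subject.size:
            if np.any(np.diff(self.subject) < 0):
                raise DataError("rows must be sorted by subject")
            bounds = self.subject_bounds()
            for a, b in zip(bounds[:-1], bounds[1:]):
                if np.any(self.start[a + 1 : b] != self.stop[a : b - 1]):
                    raise DataError("subject intervals must be contiguous")
                if self.event[a:b][:-1].any():
                    raise DataError("event must sit on a subject's final interval")

    # -- column access --------------------------------------------------

    def columns(self, names: list[str]) -> np.ndarray:
        idx = [self.covariates.index(n) for n in names]
        return self.X[:, idx]

    def exposure(self) -> np.ndarray:
        return self.stop - self.start

    # -- derived datasets ------------------------------------------------

    def with_event_times(
        self, times: np.ndarray, resolved: np.ndarray
    ) -> "RiskSetData":
        """Replace observed outcomes with simulated event times.

        Each subject's intervals are truncated at its simulated time; the
        final interval carries the event flag (censored if unresolved).
        Subjects whose simulated time is <= 0 are dropped.
        """
        times = np.asarray(times, dtype=float)
        resolved = np.asarray(resolved, dtype=bool)
        t_row = times[self.subject]
        keep = self.start < t_row
        new_stop = np.minimum(self.stop, t_row)[keep]
        new_start = self.start[keep]
        subj = self.subject[keep]
        ev = (new_stop == t_row[keep]) & resolved[subj]
        # recode subjects that survive truncation
        kept_subjects, new_codes = np.unique(subj, return_inverse=True)
        groups = self.groups.iloc[kept_subjects].reset_index(drop=True)
        return RiskSetData(
            subject=new_codes,
            start=new_start,
            stop=new_stop,
            event=ev,
            X=self.X[keep],
            covariates=list(self.covariates),
            groups=groups,
            scaling=self.scaling,
            raw_X=None if self.raw_X is None else self.raw_X[keep],
            count_threshold=self.count_threshold,
            exclusions=dict(self.exclusions),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format start,stop,event,covariates table."""
        df = pd.DataFrame(
            {
                "fish_id": self.groups["fish_id"].to_numpy()[self.subject],
                "start": self.start,
                "stop": self.stop,
                "event": self.event.astype(int),
            }
        )
        for j, name in enumerate(self.covariates):
            df[name] = self.X[:, j]
        return df


# ---------------------------------------------------------------------------
# construction from fish records
# ---------------------------------------------------------------------------


def build_counting_process(
    fish: list[FishRecord],
    cov: CovariateSeries,
    stage: str,
    covariates: tuple[str, ...] = ("temperature", "diel", "count"),
    count_threshold: float | None = None,
) -> RiskSetData:
    """Split each fish's stage exposure at covariate-change boundaries.

    Fish with missing stage timestamps (or zero-length exposure) are
    excluded and tallied in ``exclusions`` rather than censored.  A
    ``count_threshold`` adds a binary indicator covariate (count <=
    threshold) named ``count_thresh``.
    """
    if stage not in ("finding", "fishway"):
        raise ConfigurationError(f"unknown stage {stage!r}")
    names = list(covariates)
    if count_threshold is not None:
        if "count" not in names:
            raise ConfigurationError("count_threshold requires the count covariate")
        names = names + [THRESHOLD_NAME]

    rows_subject: list[np.ndarray] = []
    rows_start: list[np.ndarray] = []
    rows_stop: list[np.ndarray] = []
    rows_event: list[np.ndarray] = []
    rows_X: list[np.ndarray] = []
    group_rows: list[dict] = []
    exclusions: dict[str, int] = {}

    code = 0
    for f in fish:
        window = f.stage_window(stage)
        if window is None:
            exclusions["missing_timestamp"] = exclusions.get("missing_timestamp", 0) + 1
            continue
        a, b = window
        if b <= a:
            exclusions["zero_duration"] = exclusions.get("zero_duration", 0) + 1
            continue
        cuts = [np.array([a, b])]
        for name in covariates:
            cuts.append(cov.boundaries(name, a, b))
        edges = np.unique(np.concatenate(cuts))
        starts_cal = edges[:-1]
        try:
            cols = []
            for name in covariates:
                cols.append(cov.value(name, starts_cal, dam=f.dam, species=f.species))
        except DataError as exc:
            raise DataError(f"fish {f.fish_id}: {exc}") from exc
        Xf = np.column_stack(cols)
        if count_threshold is not None:
            count_col = Xf[:, covariates.index("count")]
            Xf = np.column_stack([Xf, (count_col <= count_threshold).astype(float)])
        m = starts_cal.size
        rows_subject.append(np.full(m, code))
        rows_start.append(edges[:-1] - a)
        rows_stop.append(edges[1:] - a)
        ev = np.zeros(m, dtype=bool)
        ev[-1] = True
        rows_event.append(ev)
        rows_X.append(Xf)
        group_rows.append(
            {
                "fish_id": f.fish_id,
                "species": f.species,
                "run": f.run,
                "dam": f.dam,
                "fishway": f.fishway,
                "entry_hour": a,
            }
        )
        code += 1

    if code == 0:
        return RiskSetData(
            subject=np.zeros(0, dtype=int),
            start=np.zeros(0),
            stop=np.zeros(0),
            event=np.zeros(0, dtype=bool),
            X=np.zeros((0, len(names))),
            covariates=names,
            groups=pd.DataFrame(columns=GROUP_COLUMNS),
            count_threshold=count_threshold,
            exclusions=exclusions,
        )

    data = RiskSetData(
        subject=np.concatenate(rows_subject),
        start=np.concatenate(rows_start),
        stop=np.concatenate(rows_stop),
        event=np.concatenate(rows_event),
        X=np.vstack(rows_X),
        covariates=names,
        groups=pd.DataFrame(group_rows, columns=GROUP_COLUMNS),
        count_threshold=count_threshold,
        exclusions=exclusions,
    )
    data.validate()
    return data


def build_simulation_template(
    fish: list[FishRecord],
    cov: CovariateSeries,
    stage: str,
    covariates: tuple[str, ...] = ("temperature", "diel", "count"),
    count_threshold: float | None = None,
    horizon_hours: float = 336.0,
    scaling: ScalingRecord | None = None,
) -> RiskSetData:
    """Event-free covariate paths for simulating new event times.

    Includes exactly the fish that ``build_counting_process`` would include
    (same subject order), but extends each path from the stage start to
    ``horizon_hours`` later (capped at season end) so a simulated event
    time is not artificially censored at the fish's own observed duration.
    Pass the ScalingRecord from the fitted data to put the template on the
    fitted covariate scale.
    """
    extended: list[FishRecord] = []
    season_end = cov.season_hours
    for f in fish:
        window = f.stage_window(stage)
        if window is None or window[1] <= window[0]:
            continue
        a = window[0]
        b = min(a + horizon_hours, season_end)
        if b <= a:
            continue
        g = FishRecord(
            fish_id=f.fish_id,
            species=f.species,
            run=f.run,
            dam=f.dam,
            fishway=f.fishway,
        )
        if stage == "finding":
            g.t_tailrace_entry, g.t_first_fishway_entry = a, b
        else:
            g.t_last_fishway_entry, g.t_fishway_exit = a, b
        extended.append(g)
    template = build_counting_process(
        extended, cov, stage, covariates=covariates, count_threshold=count_threshold
    )
    template.event[:] = False
    if scaling is not None:
        template = apply_scaling(template, scaling)
    return template


def apply_scaling(data: RiskSetData, record: ScalingRecord) -> RiskSetData:
    """Put raw-scale data onto an existing fit's covariate scale."""
    raw = data.raw_X if data.raw_X is not None else data.X
    out = replace(data, X=record.apply(raw, data.covariates))
    out.raw_X = raw.copy()
    out.scaling = record
    return out


def standardize(
    data: RiskSetData, binary: set[str] | None = None
) -> tuple[RiskSetData, ScalingRecord]:
    """Exposure-weighted standardization of continuous covariates.

    Continuous covariates are shifted/scaled to weighted mean 0 and
    population sd 1 (weights = interval exposure); binary covariates are
    left untouched.  The returned record suffices to invert the transform
    and to move coefficients between scales.
    """
    base = data.raw_X if data.raw_X is not None else data.X
    record = ScalingRecord.fit(
        base, data.covariates, weights=data.exposure(), binary=binary
    )
    out = replace(data, X=record.apply(base, data.covariates))
    out.raw_X = base.copy()
    out.scaling = record
    return out, record


# ---------------------------------------------------------------------------
# Breslow partial likelihood
# ---------------------------------------------------------------------------


class _PartialLikelihood:
    """Vectorized Breslow/Efron partial likelihood for counting-process data.

    Risk-set denominators at an event time t are computed from two
    pre-sorted suffix-cumsum tables using
        sum_{start_i < t <= stop_i} v_i
            = sum_{stop_i >= t} v_i - sum_{start_i >= t} v_i ,
    so each Newton iteration is O(n log n) regardless of risk-set sizes.
    """

    def __init__(self, start, stop, event, X, ties="breslow"):
        self.X = np.asarray(X, dtype=float)
        self.n, self.k = self.X.shape
        self.ties = ties
        start = np.asarray(start, dtype=float)
        stop = np.asarray(stop, dtype=float)
        event = np.asarray(event, dtype=bool)
        self._order_start = np.argsort(start, kind="stable")
        self._order_stop = np.argsort(stop, kind="stable")
        self._start_sorted = start[self._order_start]
        self._stop_sorted = stop[self._order_stop]
        ev_times = stop[event]
        self.event_rows = np.flatnonzero(event)
        self.te, inv = np.unique(ev_times, return_inverse=True)
        self.m = self.te.size
        self.d = np.bincount(inv, minlength=self.m).astype(float)
        self._ev_inv = inv
        self._idx_stop = np.searchsorted(self._stop_sorted, self.te, side="left")
        self._idx_start = np.searchsorted(self._start_sorted, self.te, side="left")
        # sum of covariates over event rows, grouped by event time
        Xe = self.X[self.event_rows]
        self.sumx_events = Xe.sum(axis=0)
        self._Xe = Xe
        iu, ju = np.triu_indices(self.k)
        self._iu, self._ju = iu, ju

    def _suffix_eval(self, V: np.ndarray) -> np.ndarray:
        """Risk-set sums of each column of V at every distinct event time."""
        tot_stop = np.vstack(
            [np.cumsum(V[self._order_stop][::-1], axis=0)[::-1], np.zeros((1, V.shape[1]))]
        )
        tot_start = np.vstack(
            [np.cumsum(V[self._order_start][::-1], axis=0)[::-1], np.zeros((1, V.shape[1]))]
        )
        return tot_stop[self._idx_stop] - tot_start[self._idx_start]

    def quantities(self, beta: np.ndarray):
        """(loglik, score, information) at beta."""
        k = self.k
        eta = self.X @ beta if k else np.zeros(self.n)
        shift = float(eta.max()) if self.n else 0.0
        w = np.exp(eta - shift)
        wX = w[:, None] * self.X if k else np.zeros((self.n, 0))
        wXX = (
            wX[:, self._iu] * self.X[:, self._ju] if k else np.zeros((self.n, 0))
        )
        V = np.column_stack([w[:, None], wX, wXX])
        S = self._suffix_eval(V)
        S0 = S[:, 0]
        S1 = S[:, 1 : 1 + k]
        S2p = S[:, 1 + k :]
        if np.any(S0 <= 0):
            raise ConvergenceError("empty risk set encountered")
        if self.ties == "efron" and np.any(self.d > 1):
            return self._efron(beta, eta, shift, w, wX, wXX, S0, S1, S2p)
        logS0 = np.log(S0) + shift
        loglik = float(eta[self.event_rows].sum() - np.sum(self.d * logS0))
        if k == 0:
            return loglik, np.zeros(0), np.zeros((0, 0))
        S1b = S1 / S0[:, None]
        score = self.sumx_events - (self.d[:, None] * S1b).sum(axis=0)
        packed = (self.d[:, None] * (S2p / S0[:, None])).sum(axis=0)
        info = np.zeros((k, k))
        info[self._iu, self._ju] = packed
        info = info + info.T - np.diag(np.diag(info))
        info -= (self.d[:, None, None] * (S1b[:, :, None] * S1b[:, None, :])).sum(axis=0)
        return loglik, score, info

    def _efron(self, beta, eta, shift, w, wX, wXX, S0, S1, S2p):
        """Efron tie correction; loops over distinct event times."""
        k = self.k
        loglik = float(eta[self.event_rows].sum())
        score = self.sumx_events.copy() if k else np.zeros(0)
        info = np.zeros((k, k))
        for q in range(self.m):
            rows = self.event_rows[self._ev_inv == q]
            d = int(self.d[q])
            s0e = w[rows].sum()
            s1e = wX[rows].sum(axis=0) if k else np.zeros(0)
            s2e = wXX[rows].sum(axis=0) if k else np.zeros(0)
            for ell in range(d):
                frac = ell / d
                den0 = S0[q] - frac * s0e
                loglik -= np.log(den0) + shift
                if k:
                    den1 = (S1[q] - frac * s1e) / den0
                    score -= den1
                    packed = (S2p[q] - frac * s2e) / den0
                    M = np.zeros((k, k))
                    M[self._iu, self._ju] = packed
                    M = M + M.T - np.diag(np.diag(M))
                    info += M - np.outer(den1, den1)
        return loglik, score, info

    def schoenfeld(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(event times per event row, residuals x_i - S1/S0 at beta)."""
        eta = self.X @ beta if self.k else np.zeros(self.n)
        shift = float(eta.max()) if self.n else 0.0
        w = np.exp(eta - shift)
        wX = w[:, None] * self.X
        V = np.column_stack([w[:, None], wX])
        S = self._suffix_eval(V)
        S1b = S[:, 1:] / S[:, :1]
        resid = self._Xe - S1b[self._ev_inv]
        times = self.te[self._ev_inv]
        return times, resid


@dataclass
class PHFit:
    """Fitted proportional-hazards model."""

    covariates: list[str]
    beta: np.ndarray
    cov_matrix: np.ndarray
    loglik: float
    loglik_null: float
    aicc: float
    n_subjects: int
    n_events: int
    scaling: ScalingRecord | None
    ties: str
    n_iter: int
    converged: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_matrix)) if self.beta.size else np.zeros(0)

    def coefficient(self, name: str) -> float:
        return float(self.beta[self.covariates.index(name)])

    def beta_natural(self) -> np.ndarray:
        if self.scaling is None:
            return self.beta.copy()
        return self.scaling.beta_to_natural(self.beta, self.covariates)

    def to_dict(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "beta": self.beta.tolist(),
            "beta_natural": self.beta_natural().tolist(),
            "se": self.se.tolist(),
            "cov_matrix": self.cov_matrix.tolist(),
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "aicc": self.aicc,
            "n_subjects": self.n_subjects,
            "n_events": self.n_events,
            "ties": self.ties,
            "scaling": None if self.scaling is None else self.scaling.to_dict(),
        }


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[1] == 0:
        return
    Xc = X - X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    degenerate = [n for n, v in zip(names, norms) if v < 1e-10]
    if degenerate:
        raise RankDeficiencyError(degenerate)
    r = np.linalg.matrix_rank(Xc)
    if r < X.shape[1]:
        # identify a collinear set via QR pivoting
        from scipy.linalg import qr

        _, R, piv = qr(Xc, pivoting=True, mode="economic")
        diag = np.abs(np.diag(R))
        bad = piv[diag < diag[0] * 1e-10] if diag.size else piv
        raise RankDeficiencyError([names[j] for j in np.atleast_1d(bad)])


def aicc_from(loglik: float, k: int, n: int) -> float:
    """Small-sample AIC with n = number of events."""
    aic = -2.0 * loglik + 2.0 * k
    if n > k + 1:
        return aic + (2.0 * k * (k + 1)) / (n - k - 1)
    return np.inf


def fit_ph(
    data: RiskSetData,
    covariate_set: list[str] | None = None,
    ties: str = "breslow",
    max_iter: int = 60,
    score_tol: float = 1e-6,
    loglik_tol: float = 1e-10,
    init: np.ndarray | None = None,
) -> PHFit:
    """Maximize the partial likelihood by Newton-Raphson with step-halving.

    Converges when the score max-norm drops below ``score_tol`` and the
    relative log-likelihood change below ``loglik_tol``.  Monotone
    likelihood (separation) raises ConvergenceError.
    """
    if ties not in ("breslow", "efron"):
        raise ConfigurationError(f"unknown ties method {ties!r}")
    names = list(data.covariates) if covariate_set is None else list(covariate_set)
    missing = [n for n in names if n not in data.covariates]
    if missing:
        raise ConfigurationError(f"unknown covariates: {missing}")
    if data.n_events < 1:
        raise DataError("need at least one event to fit")
    X = data.columns(names)
    _check_rank(X[data.event], names)
    pl = _PartialLikelihood(data.start, data.stop, data.event, X, ties=ties)
    k = len(names)
    beta = np.zeros(k) if init is None else np.asarray(init, dtype=float).copy()

    loglik, score, info = pl.quantities(beta)
    n_iter = 0
    converged = k == 0
    for n_iter in range(1, max_iter + 1):
        if k == 0:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # step halving to guarantee ascent
        factor = 1.0
        for _ in range(40):
            cand = beta + factor * step
            ll_new, sc_new, in_new = pl.quantities(cand)
            if ll_new >= loglik - 1e-12:
                break
            factor *= 0.5
        else:
            raise ConvergenceError("step halving failed to find an ascent step")
        rel = abs(ll_new - loglik) / max(abs(loglik), 1.0)
        beta, score, info = cand, sc_new, in_new
        loglik = ll_new
        if np.max(np.abs(beta)) > 50.0:
            raise ConvergenceError(
                "coefficients diverged (|beta| > 50): monotone likelihood / "
                "separation suspected"
            )
        if np.max(np.abs(score), initial=0.0) < score_tol and rel < loglik_tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations "
            f"(score max-norm {np.max(np.abs(score), initial=0.0):.3g})"
        )

    if k:
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"information not invertible: {exc}") from exc
        cov = (cov + cov.T) / 2.0
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
        if np.any(ses > 1e3):
            bad = [names[j] for j in np.flatnonzero(ses > 1e3)]
            raise ConvergenceError(
                "monotone likelihood (separation) suspected: essentially flat "
                f"information for {bad} (standard error > 1e3)"
            )
    else:
        cov = np.zeros((0, 0))
    ll_null = pl.quantities(np.zeros(k))[0] if k else loglik
    return PHFit(
        covariates=names,
        beta=beta,
        cov_matrix=cov,
        loglik=loglik,
        loglik_null=ll_null,
        aicc=aicc_from(loglik, k, data.n_events),
        n_subjects=data.n_subjects,
        n_events=data.n_events,
        scaling=data.scaling,
        ties=ties,
        n_iter=n_iter,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# baseline hazard and simulation
# ---------------------------------------------------------------------------


def breslow_baseline(fit: PHFit, data: RiskSetData) -> BaselineHazard:
    """Breslow step estimate: increment d(t) / sum_{at risk} exp(X beta).

    The tail beyond the last event time is extrapolated at the mean hazard
    rate over the final quartile of event times so that simulation has
    support past the observed data.
    """
    if data.n_events == 0:
        return BaselineHazard(np.zeros(0), np.zeros(0), tail_rate=0.0)
    X = data.columns(fit.covariates)
    pl = _PartialLikelihood(data.start, data.stop, data.event, X, ties="breslow")
    eta = X @ fit.beta if fit.beta.size else np.zeros(data.n_intervals)
    shift = float(eta.max())
    w = np.exp(eta - shift)
    S0 = pl._suffix_eval(w[:, None])[:, 0] * np.exp(shift)
    increments = pl.d / S0
    base = BaselineHazard(pl.te, increments, tail_rate=0.0)
    # constant-rate tail: mean rate over the final quartile of event times
    tmax = pl.te[-1]
    tq = np.quantile(pl.te, 0.75)
    cum = np.cumsum(increments)
    if tmax > tq:
        lam_q = np.interp(tq, pl.te, cum)
        tail = (cum[-1] - lam_q) / (tmax - tq)
    else:
        tail = cum[-1] / tmax if tmax > 0 else 0.0
    return BaselineHazard(pl.te, increments, tail_rate=float(max(tail, 0.0)))


@dataclass
class SimulatedTimes:
    """Event times drawn from a fitted model over template covariate paths."""

    times: np.ndarray
    resolved: np.ndarray

    @property
    def n_unresolved(self) -> int:
        return int((~self.resolved).sum())


def simulate_event_times(
    fit: PHFit,
    base: BaselineHazard,
    template: RiskSetData,
    seed: int | np.random.Generator = 0,
) -> SimulatedTimes:
    """Draw one event time per template subject by inverting its cumulative
    hazard Lambda_i(t) = int exp(X_i(u) beta) dLambda0(u) at an independent
    standard-exponential draw."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = template.columns(fit.covariates)
    loghr = X @ fit.beta if fit.beta.size else np.zeros(template.n_intervals)
    bounds = template.subject_bounds()
    draws = rng.exponential(size=template.n_subjects)
    times, resolved = draw_event_times(
        base, template.start, template.stop, loghr, bounds, draws
    )
    return SimulatedTimes(times=times, resolved=resolved)


# ---------------------------------------------------------------------------
# proportional-hazards diagnostic
# ---------------------------------------------------------------------------


@dataclass
class PHCheckResult:
    """Advisory score-process (Schoenfeld trend) summary; never gates fits."""

    covariates: list[str]
    statistic: np.ndarray
    p_value: np.ndarray
    n_events: int
    skipped: bool = False


def ph_assumption_check(
    fit: PHFit,
    data: RiskSetData,
    n_perm: int = 199,
    seed: int | np.random.Generator = 0,
    min_events: int = 10,
) -> PHCheckResult:
    """Permutation test for a time trend in Schoenfeld residuals.

    The statistic per covariate is the Pearson correlation between the
    residual and the rank of the event time; the p-value comes from
    permuting residual order against times.  Advisory only.
    """
    if data.n_events < min_events:
        warnings.warn(
            f"PH assumption check skipped: only {data.n_events} events "
            f"(< {min_events})",
            stacklevel=2,
        )
        k = len(fit.covariates)
        return PHCheckResult(
            covariates=list(fit.covariates),
            statistic=np.full(k, np.nan),
            p_value=np.full(k, np.nan),
            n_events=data.n_events,
            skipped=True,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = data.columns(fit.covariates)
    pl = _PartialLikelihood(data.start, data.stop, data.event, X, ties="breslow")
    times, resid = pl.schoenfeld(fit.beta)
    order = np.argsort(np.argsort(times)).astype(float)  # rank of event time
    order = (order - order.mean()) / max(order.std(), 1e-12)
    rc = resid - resid.mean(axis=0)
    sd = rc.std(axis=0)
    sd[sd == 0] = 1.0
    rc = rc / sd
    n = len(times)
    stat = (rc * order[:, None]).sum(axis=0) / n
    perm_stats = np.empty((n_perm, rc.shape[1]))
    for b in range(n_perm):
        perm = rng.permutation(n)
        perm_stats[b] = (rc[perm] * order[:, None]).sum(axis=0) / n
    p = (1.0 + (np.abs(perm_stats) >= np.abs(stat)).sum(axis=0)) / (n_perm + 1.0)
    return PHCheckResult(
        covariates=list(fit.covariates),
        statistic=stat,
        p_value=p,
        n_events=n,
    )
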