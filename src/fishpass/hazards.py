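"""Hazard representations and exact event-time simulation.

Two baseline-hazard flavours share one interface (``cumhaz`` /
``invert_cum``): a piecewise-constant rate function used by the synthetic
generator and for closed-form checks, and the step (atomic) cumulative
hazard produced by the Breslow estimator.  ``draw_event_times`` inverts a
subject-specific cumulative hazard built from a piecewise-constant
covariate path at an independent standard-exponential draw, with no
discretization error beyond the step structure itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError


@dataclass
class PiecewiseConstantHazard:
    """Rate function constant on [breaks[i], breaks[i+1]); last piece to +inf."""

    breaks: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.breaks = np.asarray(self.breaks, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.breaks.ndim != 1 or self.breaks.size == 0 or self.breaks[0] != 0.0:
            raise ConfigurationError("breaks must start at 0")
        if np.any(np.diff(self.breaks) <= 0):
            raise ConfigurationError("breaks must be strictly increasing")
        if self.rates.shape != self.breaks.shape:
            raise ConfigurationError("rates must align with breaks")
        if np.any(self.rates < 0) or not np.all(np.isfinite(self.rates)):
            raise ConfigurationError("rates must be finite and >= 0")
        # cumulative hazard at each break
        seg = self.rates[:-1] * np.diff(self.breaks)
        self._cum = np.concatenate([[0.0], np.cumsum(seg)])

    @classmethod
    def constant(cls, rate: float) -> "PiecewiseConstantHazard":
        return cls(np.array([0.0]), np.array([float(rate)]))

    def cumhaz(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.breaks, t, side="right") - 1, 0, None)
        return self._cum[idx] + self.rates[idx] * (t - self.breaks[idx])

    def invert_cum(self, c: np.ndarray) -> np.ndarray:
        """Earliest t with cumulative hazard >= c (inf if never reached)."""
        c = np.asarray(c, dtype=float)
        idx = np.clip(np.searchsorted(self._cum, c, side="right") - 1, 0, None)
        rate = self.rates[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            extra = (c - self._cum[idx]) / rate
        out = self.breaks[idx] + extra
        # zero-rate final segment can never accumulate the residual
        out = np.where((rate == 0) & (c > self._cum[idx]), np.inf, out)
        return np.where(c <= 0, 0.0, out)


@dataclass
class BaselineHazard:
    """Breslow step cumulative hazard: atoms at event times.

    ``tail_rate`` extrapolates a constant hazard beyond the last atom so a
    simulation can spend hazard past the observed support; subjects whose
    draw is still unspent at the end of their covariate path are flagged
    unresolved by the caller.
    """

    times: np.ndarray
    increments: np.ndarray
    tail_rate: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.increments = np.asarray(self.increments, dtype=float)
        if self.times.shape != self.increments.shape:
            raise ConfigurationError("times and increments must align")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("atom times must be strictly increasing")
        if np.any(self.increments <= 0):
            raise ConfigurationError("increments must be > 0")
        if self.tail_rate < 0:
            raise ConfigurationError("tail_rate must be >= 0")
        self._cum = np.cumsum(self.increments)

    @property
    def support_end(self) -> float:
        return float(self.times[-1]) if self.times.size else 0.0

    def cumulative(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, Lambda0(times)) step function; Lambda0(0) = 0."""
        return self.times.copy(), self._cum.copy()

    def cumhaz(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            return self.tail_rate * np.maximum(t, 0.0)
        idx = np.searchsorted(self.times, t, side="right")
        base = np.where(idx > 0, self._cum[np.clip(idx - 1, 0, None)], 0.0)
        return base + self.tail_rate * np.maximum(t - self.support_end, 0.0)

    def invert_cum(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        if self.times.size == 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(c <= 0, 0.0, c / self.tail_rate if self.tail_rate > 0 else np.inf)
        total = self._cum[-1]
        m = np.searchsorted(self._cum, c, side="left")
        inside = c <= total
        t_atom = self.times[np.clip(m, 0, self.times.size - 1)]
        with np.errstate(divide="ignore", invalid="ignore"):
            t_tail = self.support_end + (c - total) / self.tail_rate
        t_tail = np.where(self.tail_rate > 0, t_tail, np.inf)
        return np.where(inside, t_atom, t_tail)


def draw_event_times(
    baseline,
    start: np.ndarray,
    stop: np.ndarray,
    loghr: np.ndarray,
    subject_bounds: np.ndarray,
    exp_draws: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert subject cumulative hazards at standard-exponential draws.

    Intervals must be sorted by subject with contiguous rows per subject;
    ``subject_bounds`` holds the row boundaries (length n_subjects + 1).
    Returns (event_times, resolved); unresolved subjects (exponential draw
    unspent when their covariate path ends) get time = path end.
    """
    start = np.asarray(start, dtype=float)
    stop = np.asarray(stop, dtype=float)
    g = np.exp(np.asarray(loghr, dtype=float))
    ch_start = baseline.cumhaz(start)
    inc = g * (baseline.cumhaz(stop) - ch_start)
    cs = np.cumsum(inc)
    a = subject_bounds[:-1]
    b = subject_bounds[1:]
    offsets = np.where(a > 0, cs[np.clip(a - 1, 0, None)], 0.0)
    target = offsets + np.asarray(exp_draws, dtype=float)
    j = np.searchsorted(cs, target, side="left")
    resolved = j < b
    jc = np.minimum(j, np.maximum(b - 1, 0))
    prev = np.where(jc > 0, cs[np.clip(jc - 1, 0, None)], 0.0)
    remaining = np.maximum(target - prev, 0.0)
    c_target = ch_start[jc] + remaining / g[jc]
    t = baseline.invert_cum(c_target)
    t = np.minimum(t, stop[jc])  # guard float spill past the interval end
    path_end = stop[np.maximum(b - 1, 0)]
    times = np.where(resolved, t, path_end)
    return times, resolved
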