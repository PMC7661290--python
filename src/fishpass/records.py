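"""Core data records: per-fish event histories and time-indexed covariates.

All times are hours from a per-season origin (hour 0 = midnight starting
day 0).  Daily covariates are step functions constant on [24*d, 24*(d+1));
the diel indicator is 1 inside the configured day window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .errors import DataError

HOURS_PER_DAY = 24.0

#: ordered timestamp fields of a FishRecord
STAGE_FIELDS = (
    "t_tailrace_entry",
    "t_first_fishway_entry",
    "t_last_fishway_entry",
    "t_fishway_exit",
)


@dataclass
class FishRecord:
    """One fish's stage timestamps (hours from season origin) and labels.

    Missing timestamps are ``None``.  Present timestamps must be ordered
    tailrace entry <= first fishway entry <= last fishway entry <= exit.
    """

    fish_id: str
    species: str
    run: str = "none"
    dam: str = "TD"
    fishway: str = "main"
    t_tailrace_entry: float | None = None
    t_first_fishway_entry: float | None = None
    t_last_fishway_entry: float | None = None
    t_fishway_exit: float | None = None
    committed_first_attempt: bool | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        present = [
            (name, getattr(self, name))
            for name in STAGE_FIELDS
            if getattr(self, name) is not None
        ]
        times = [t for _, t in present]
        if any(not np.isfinite(t) for t in times):
            raise DataError(f"fish {self.fish_id}: non-finite timestamp")
        if any(a > b for a, b in zip(times, times[1:])):
            raise DataError(f"fish {self.fish_id}: timestamps out of order")
        if (
            self.committed_first_attempt is not None
            and self.t_first_fishway_entry is not None
            and self.t_last_fishway_entry is not None
        ):
            same = self.t_first_fishway_entry == self.t_last_fishway_entry
            if self.committed_first_attempt != same:
                raise DataError(
                    f"fish {self.fish_id}: committed_first_attempt inconsistent "
                    "with fishway entry timestamps"
                )

    def stage_window(self, stage: str) -> tuple[float, float] | None:
        """(start, end) hours of a stage, or None if a timestamp is missing."""
        if stage == "finding":
            a, b = self.t_tailrace_entry, self.t_first_fishway_entry
        elif stage == "fishway":
            a, b = self.t_last_fishway_entry, self.t_fishway_exit
        else:
            raise ValueError(f"unknown stage {stage!r}")
        if a is None or b is None:
            return None
        return float(a), float(b)


@dataclass
class CovariateSeries:
    """Environmental and count covariates on a regular season grid.

    ``temperature`` and ``spill`` hold one value per day; ``daily_count``
    maps (dam, species) to one value per day.  The diel indicator is
    derived from ``day_window`` on demand.
    """

    season_days: int
    temperature: np.ndarray
    spill: np.ndarray
    daily_count: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    day_window: tuple[float, float] = (6.0, 18.0)

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.spill = np.asarray(self.spill, dtype=float)
        if self.season_days <= 0:
            raise DataError("season_days must be positive")
        for name in ("temperature", "spill"):
            arr = getattr(self, name)
            if arr.shape != (self.season_days,):
                raise DataError(
                    f"{name} must have one value per day "
                    f"({arr.shape[0]} != {self.season_days})"
                )
            if not np.all(np.isfinite(arr)):
                raise DataError(f"{name} contains non-finite values")
        clean = {}
        for key, arr in self.daily_count.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.season_days,):
                raise DataError(f"daily_count[{key}] has wrong length")
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise DataError(f"daily_count[{key}] must be finite and >= 0")
            clean[key] = arr
        self.daily_count = clean

    # -- lookup ---------------------------------------------------------

    @property
    def season_hours(self) -> float:
        return self.season_days * HOURS_PER_DAY

    def _daily_lookup(self, series: np.ndarray, hours: np.ndarray) -> np.ndarray:
        day = np.floor(np.asarray(hours, dtype=float) / HOURS_PER_DAY).astype(int)
        if np.any(day < 0) or np.any(day >= self.season_days):
            raise DataError(
                "covariate lookup outside season coverage "
                f"(day range {day.min()}..{day.max()}, season {self.season_days} d)"
            )
        return series[day]

    def value(
        self,
        name: str,
        hours: np.ndarray,
        dam: str | None = None,
        species: str | None = None,
    ) -> np.ndarray:
        """Step-function value of covariate ``name`` at calendar ``hours``."""
        hours = np.atleast_1d(np.asarray(hours, dtype=float))
        if name == "temperature":
            return self._daily_lookup(self.temperature, hours)
        if name == "spill":
            return self._daily_lookup(self.spill, hours)
        if name == "diel":
            tod = np.mod(hours, HOURS_PER_DAY)
            lo, hi = self.day_window
            return ((tod >= lo) & (tod < hi)).astype(float)
        if name == "count":
            key = (dam, species)
            if key not in self.daily_count:
                raise DataError(f"no daily counts for dam/species {key}")
            return self._daily_lookup(self.daily_count[key], hours)
        raise KeyError(f"unknown covariate {name!r}")

    def boundaries(self, name: str, t0: float, t1: float) -> np.ndarray:
        """Change points of covariate ``name`` strictly inside (t0, t1)."""
        if name in ("temperature", "spill", "count"):
            first = np.ceil(t0 / HOURS_PER_DAY) * HOURS_PER_DAY
            pts = np.arange(first, t1, HOURS_PER_DAY)
        elif name == "diel":
            lo, hi = self.day_window
            d0 = np.floor(t0 / HOURS_PER_DAY)
            d1 = np.floor(t1 / HOURS_PER_DAY)
            days = np.arange(d0, d1 + 1)
            pts = np.unique(
                np.concatenate([days * HOURS_PER_DAY + lo, days * HOURS_PER_DAY + hi])
            )
        else:
            raise KeyError(f"unknown covariate {name!r}")
        return pts[(pts > t0) & (pts < t1)]

    def with_counts(
        self, counts: dict[tuple[str, str], np.ndarray]
    ) -> "CovariateSeries":
        """Copy of the series with ``daily_count`` replaced."""
        return CovariateSeries(
            season_days=self.season_days,
            temperature=self.temperature.copy(),
            spill=self.spill.copy(),
            daily_count={k: np.asarray(v, dtype=float).copy() for k, v in counts.items()},
            day_window=self.day_window,
        )


def record_fields() -> list[str]:
    """Column order used by the CSV writers."""
    return [f.name for f in fields(FishRecord)]
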