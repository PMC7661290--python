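"""CSV/JSON readers and writers for the package's plain-text formats.

Columns are hours-from-season-origin (documented in a ``# fishpass`` header
comment line) so every artifact stays text-only and diff-friendly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .records import CovariateSeries, FishRecord, record_fields
from .survival import RiskSetData

FISH_HEADER = "# fishpass fish events v1: times are hours from season origin\n"
COUNT_HEADER = "# fishpass daily counts v1: day index from season origin\n"
COV_HEADER = "# fishpass covariates v1: one row per day\n"


def _write_csv(df: pd.DataFrame, path, header: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# -- fish event tables ------------------------------------------------------


def write_fish_events(fish: list[FishRecord], path) -> None:
    rows = []
    for f in fish:
        rows.append({name: getattr(f, name) for name in record_fields()})
    _write_csv(pd.DataFrame(rows, columns=record_fields()), path, FISH_HEADER)


def read_fish_events(path) -> list[FishRecord]:
    df = _read_csv(path)
    missing = set(record_fields()) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        kwargs = {}
        for name in record_fields():
            val = row[name]
            if isinstance(val, float) and np.isnan(val):
                val = None
            if name == "committed_first_attempt" and val is not None:
                val = bool(val)
            kwargs[name] = val
        try:
            out.append(FishRecord(**kwargs))
        except (DataError, TypeError) as exc:
            raise DataError(f"{path} line {i + 2}: {exc}") from exc
    return out


# -- daily counts -----------------------------------------------------------


def write_daily_counts(counts: dict[tuple[str, str], np.ndarray], path) -> None:
    frames = []
    for (dam, species), series in sorted(counts.items()):
        frames.append(
            pd.DataFrame(
                {
                    "day": np.arange(len(series)),
                    "dam": dam,
                    "species": species,
                    "count": np.asarray(series),
                }
            )
        )
    _write_csv(pd.concat(frames, ignore_index=True), path, COUNT_HEADER)


def read_daily_counts(path) -> dict[tuple[str, str], np.ndarray]:
    df = _read_csv(path)
    for col in ("day", "dam", "species", "count"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    out: dict[tuple[str, str], np.ndarray] = {}
    for (dam, species), grp in df.groupby(["dam", "species"]):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy()
        if not np.array_equal(days, np.arange(days.size)):
            raise DataError(f"{path}: counts for ({dam}, {species}) have day gaps")
        out[(dam, species)] = grp["count"].to_numpy(dtype=float)
    return out


# -- covariate series -------------------------------------------------------


def write_covariates(cov: CovariateSeries, path) -> None:
    df = pd.DataFrame(
        {
            "day": np.arange(cov.season_days),
            "temperature": cov.temperature,
            "spill": cov.spill,
        }
    )
    meta = (
        COV_HEADER.rstrip("\n")
        + f" day_window={cov.day_window[0]}-{cov.day_window[1]}\n"
    )
    _write_csv(df, path, meta)


def read_covariates(
    path, counts: dict[tuple[str, str], np.ndarray] | None = None
) -> CovariateSeries:
    with open(path) as fh:
        first = fh.readline()
    window = (6.0, 18.0)
    if "day_window=" in first:
        spec = first.split("day_window=")[1].strip()
        lo, hi = spec.split("-")
        window = (float(lo), float(hi))
    df = _read_csv(path)
    for col in ("day", "temperature", "spill"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    df = df.sort_values("day")
    return CovariateSeries(
        season_days=len(df),
        temperature=df["temperature"].to_numpy(dtype=float),
        spill=df["spill"].to_numpy(dtype=float),
        daily_count=counts or {},
        day_window=window,
    )


# -- risk-set long format ---------------------------------------------------


def write_risk_sets(data: RiskSetData, path) -> None:
    _write_csv(data.to_frame(), path, "# fishpass risk sets v1 (start,stop] hours\n")


def read_risk_sets(path) -> RiskSetData:
    """Reconstruct RiskSetData from the long start,stop,event CSV dialect."""
    df = _read_csv(path)
    for col in ("fish_id", "start", "stop", "event"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    covariates = [
        c for c in df.columns if c not in ("fish_id", "start", "stop", "event")
    ]
    ids = df["fish_id"].astype(str)
    codes, uniques = pd.factorize(ids, sort=False)
    df = df.assign(_code=codes).sort_values(["_code", "start"], kind="stable")
    groups = pd.DataFrame(
        {
            "fish_id": uniques,
            "species": "unknown",
            "run": "none",
            "dam": "unknown",
            "fishway": "unknown",
            "entry_hour": np.nan,
        }
    )
    data = RiskSetData(
        subject=df["_code"].to_numpy(),
        start=df["start"].to_numpy(dtype=float),
        stop=df["stop"].to_numpy(dtype=float),
        event=df["event"].to_numpy(dtype=bool),
        X=df[covariates].to_numpy(dtype=float) if covariates else
        np.zeros((len(df), 0)),
        covariates=covariates,
        groups=groups,
    )
    data.validate()
    return data


# -- JSON helpers -----------------------------------------------------------


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"cannot serialize {type(obj).__name__}")
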