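"""Ingestion of raw log-in events into daily binary engagement matrices.

A participant's engagement with a web intervention is reduced to a 0/1
indicator per day: 1 if at least one page-opening event was logged that
calendar day, 0 otherwise. Day 1 is the enrollment (randomization) date and
the default horizon is 365 days, so each participant contributes a binary
series of fixed length regardless of how often they actually logged in.

Input files are delimited text (CSV, or TSV by extension); column names are
configurable through :class:`Dialect`. Calendar dates are compared on the
event's recorded local date — no timezone arithmetic is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Dialect",
    "DailyEngagementMatrix",
    "BinarizeDiagnostics",
    "ConfigError",
    "RecordError",
    "FormatError",
    "read_login_events",
    "read_enrollment",
    "binarize_daily",
    "weekly_counts",
    "write_matrix",
    "read_matrix",
]


class ConfigError(ValueError):
    """A required column or configuration value is missing or invalid."""


class RecordError(ValueError):
    """One or more input records violate the data contract."""


class FormatError(ValueError):
    """A persisted artifact does not match its expected on-disk format."""


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping for delimited input files."""

    user_id: str = "user_id"
    event_time: str = "event_time"
    enrollment_date: str = "enrollment_date"


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


def read_login_events(path: str | Path, dialect: Dialect = Dialect()) -> pd.DataFrame:
    """Read a log-in event file into a table with ``user_id`` and ``event_time``.

    Every row must carry a non-empty user id and a parseable timestamp
    (date required, time-of-day optional). Rows are kept in file order;
    duplicate events are allowed — they collapse during binarization.

    Raises
    ------
    ConfigError
        if a required column is absent.
    RecordError
        listing the 1-based data-row numbers of unparseable records.
    """
    raw = _read_delimited(path)
    _require_columns(raw, [dialect.user_id, dialect.event_time], path)
    events = pd.DataFrame(
        {
            "user_id": raw[dialect.user_id].str.strip(),
            "event_time": pd.to_datetime(raw[dialect.event_time], errors="coerce", format="mixed"),
        }
    )
    bad_time = events.index[events["event_time"].isna()].tolist()
    bad_user = events.index[events["user_id"] == ""].tolist()
    problems = []
    if bad_time:
        problems.append(f"unparseable {dialect.event_time!r} in data row(s) {[i + 1 for i in bad_time[:20]]}")
    if bad_user:
        problems.append(f"empty {dialect.user_id!r} in data row(s) {[i + 1 for i in bad_user[:20]]}")
    if problems:
        raise RecordError(f"{path}: " + "; ".join(problems))
    return events


def read_enrollment(path: str | Path, dialect: Dialect = Dialect()) -> pd.DataFrame:
    """Read the per-user enrollment table (one row per user)."""
    raw = _read_delimited(path)
    _require_columns(raw, [dialect.user_id, dialect.enrollment_date], path)
    enr = pd.DataFrame(
        {
            "user_id": raw[dialect.user_id].str.strip(),
            "enrollment_date": pd.to_datetime(raw[dialect.enrollment_date], errors="coerce", format="mixed"),
        }
    )
    bad = enr.index[enr["enrollment_date"].isna()].tolist()
    if bad:
        raise RecordError(f"{path}: unparseable enrollment date in data row(s) {[i + 1 for i in bad[:20]]}")
    dup = enr["user_id"][enr["user_id"].duplicated()].unique().tolist()
    if dup:
        raise RecordError(f"{path}: duplicate user_id(s) {dup[:10]}")
    return enr


@dataclass
class DailyEngagementMatrix:
    """N users x D days of binary log-in indicators; day 1 = enrollment date."""

    user_ids: list[str]
    values: np.ndarray  # (N, D) of {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if len(self.user_ids) != self.values.shape[0]:
            raise ValueError("user_ids length must match number of rows")
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            raise ValueError("engagement values must be 0 or 1")

    @property
    def n_users(self) -> int:
        return self.values.shape[0]

    @property
    def horizon_days(self) -> int:
        return self.values.shape[1]


@dataclass
class BinarizeDiagnostics:
    """Counts of events used and dropped during binarization, per reason."""

    n_events: int = 0
    n_used: int = 0
    n_before_enrollment: int = 0
    n_after_horizon: int = 0

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "n_used": self.n_used,
            "n_before_enrollment": self.n_before_enrollment,
            "n_after_horizon": self.n_after_horizon,
        }


def binarize_daily(
    events: pd.DataFrame,
    enrollment: pd.DataFrame,
    horizon_days: int = 365,
) -> tuple[DailyEngagementMatrix, BinarizeDiagnostics]:
    """Collapse log-in events into an N x ``horizon_days`` binary matrix.

    Cell ``(i, d)`` is 1 iff user *i* has at least one event on calendar
    date ``enrollment_date(i) + (d - 1)`` for d in 1..horizon_days. Events
    before enrollment or after the horizon are dropped and counted in the
    returned diagnostics. Enrolled users with no events keep an all-zero
    row; row order follows the enrollment table.
    """
    if horizon_days < 1:
        raise ValueError(f"horizon_days must be >= 1, got {horizon_days}")
    user_ids = enrollment["user_id"].tolist()
    row_of = {u: i for i, u in enumerate(user_ids)}
    unknown = sorted(set(events["user_id"]) - set(user_ids))
    if unknown:
        raise RecordError(f"events reference user(s) not in enrollment table: {unknown[:10]}")

    diag = BinarizeDiagnostics(n_events=len(events))
    values = np.zeros((len(user_ids), horizon_days), dtype=np.int8)
    if len(events):
        enr_date = enrollment.set_index("user_id")["enrollment_date"].dt.normalize()
        ev_date = events["event_time"].dt.normalize()
        day = (ev_date - events["user_id"].map(enr_date).to_numpy()).dt.days.to_numpy() + 1
        rows = events["user_id"].map(row_of).to_numpy()
        before = day < 1
        after = day > horizon_days
        keep = ~(before | after)
        diag.n_before_enrollment = int(before.sum())
        diag.n_after_horizon = int(after.sum())
        diag.n_used = int(keep.sum())
        values[rows[keep], day[keep] - 1] = 1
    return DailyEngagementMatrix(user_ids, values), diag


def weekly_counts(matrix: DailyEngagementMatrix) -> np.ndarray:
    """Aggregate daily indicators to N x 52 weekly log-in counts (0..7).

    Week *w* covers days ``7(w-1)+1 .. 7w``; day 365 (and anything beyond
    day 364) is excluded so all 52 weeks are comparable 7-day blocks.
    """
    if matrix.horizon_days < 364:
        raise ValueError(f"need at least 364 days, got {matrix.horizon_days}")
    block = matrix.values[:, :364].reshape(matrix.n_users, 52, 7)
    return block.sum(axis=2).astype(np.int64)


def write_matrix(matrix: DailyEngagementMatrix, path: str | Path) -> None:
    """Persist a daily engagement matrix as CSV (user_id, day_001..day_D)."""
    width = max(3, len(str(matrix.horizon_days)))
    cols = [f"day_{d + 1:0{width}d}" for d in range(matrix.horizon_days)]
    df = pd.DataFrame(matrix.values, columns=cols)
    df.insert(0, "user_id", matrix.user_ids)
    df.to_csv(path, index=False)


def read_matrix(path: str | Path) -> DailyEngagementMatrix:
    """Read a matrix written by :func:`write_matrix`; bit-exact round trip."""
    df = _read_delimited(path)
    if "user_id" not in df.columns:
        raise FormatError(f"{path}: missing user_id column")
    day_cols = [c for c in df.columns if c.startswith("day_")]
    if not day_cols:
        raise FormatError(f"{path}: no day_* columns found")
    day_cols = sorted(day_cols, key=lambda c: int(c.split("_")[1]))
    user_ids = df["user_id"].tolist()
    raw = df[day_cols].to_numpy(dtype=str)
    bad = ~np.isin(raw, ("0", "1"))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: non-binary value {raw[i, j]!r} at user {user_ids[i]!r}, column {day_cols[j]}"
        )
    values = (raw == "1").astype(np.int8)
    return DailyEngagementMatrix(user_ids, values)
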