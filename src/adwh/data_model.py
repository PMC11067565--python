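"""Domain types and delimited-text I/O for the identified data store.

The identified side of the warehouse is modelled as two tables:

* **measurements** — one row per raw sensor/app observation
  (``user_id, metric_name, timestamp, value``);
* **static profiles** — one row per user with time-invariant attributes
  (``user_id`` plus arbitrary attribute columns), some of which may be
  flagged as direct identifiers (name, e-mail, ...).

Both are read from and written to delimited text.  In memory the bulk
containers are :class:`pandas.DataFrame` objects with fixed column names;
the row-level dataclasses (:class:`MeasurementRecord`,
:class:`StaticProfile`, :class:`WarehouseRecord`) are the record-at-a-time
view used by small APIs and tests.

Timestamps are ISO-8601.  Naive timestamps are interpreted as UTC so that
period (day/week/month) assignment is deterministic across machines.
Rows that cannot be parsed are rejected *and reported* with their line
numbers — never silently dropped — because the surrounding framework's
safety posture depends on an audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

MEASUREMENT_COLUMNS = ("user_id", "metric_name", "timestamp", "value")

#: Generalized category used for missing attribute values.
MISSING_CATEGORY = "∅"


@dataclass(frozen=True)
class Dialect:
    """Column naming / delimiter configuration for the identified store."""

    delimiter: str = ","
    user_id: str = "user_id"
    metric_name: str = "metric_name"
    timestamp: str = "timestamp"
    value: str = "value"


@dataclass(frozen=True)
class MeasurementRecord:
    """One raw observation: a user, a metric, an instant and a finite value."""

    user_id: str
    metric_name: str
    timestamp: pd.Timestamp
    value: float

    def __post_init__(self) -> None:
        if not self.user_id:
            raise ValueError("user_id must be non-empty")
        if not np.isfinite(self.value):
            raise ValueError(f"value must be finite, got {self.value!r}")
        ts = pd.Timestamp(self.timestamp)
        if ts.tzinfo is None:
            ts = ts.tz_localize("UTC")
        object.__setattr__(self, "timestamp", ts)


@dataclass(frozen=True)
class StaticProfile:
    """A user's time-invariant attributes — the quasi-identifier surface.

    ``identifier_flags`` marks attributes that are direct identifiers and
    must be suppressed before any anonymity accounting.
    """

    user_id: str
    attributes: Mapping[str, object]
    identifier_flags: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.user_id:
            raise ValueError("user_id must be non-empty")


@dataclass(frozen=True)
class WarehouseRecord:
    """A sanitized row eligible for the anonymous warehouse.

    ``anon_id`` is a random 128-bit identifier; the only mapping back to a
    user id lives in an in-memory :class:`~adwh.export_engine.PseudonymTable`
    that is never serialized with the warehouse output.
    """

    anon_id: str
    metric_name: str
    period_start: str  # ISO date
    period_length: str  # ISO-8601 duration, e.g. "P7D"
    bucket_value: float


@dataclass
class Cohort:
    """An identified cohort: static profiles plus raw measurements.

    ``profiles`` has a ``user_id`` column plus one column per static
    attribute; ``measurements`` has the four measurement columns.
    Every measurement's user should appear in ``profiles``
    (:func:`validate_cohort` reports violations without mutating anything).
    """

    profiles: pd.DataFrame
    measurements: pd.DataFrame
    identifier_columns: tuple[str, ...] = ()

    @property
    def n_users(self) -> int:
        return int(self.profiles["user_id"].nunique())

    def profile_records(self) -> list[StaticProfile]:
        attrs = [c for c in self.profiles.columns if c != "user_id"]
        flags = {c: c in self.identifier_columns for c in attrs}
        return [
            StaticProfile(row["user_id"], {c: row[c] for c in attrs}, flags)
            for _, row in self.profiles.iterrows()
        ]


@dataclass(frozen=True)
class RejectedRow:
    line_number: int  # 1-based, counting the header as line 1
    reason: str


@dataclass
class TableReadResult:
    """A parsed table plus the audit trail of rejected rows."""

    frame: pd.DataFrame
    rejected: list[RejectedRow]

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _read_raw(path, delimiter: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def read_measurements(path, dialect: Dialect = Dialect()) -> TableReadResult:
    """Read a measurements table, rejecting malformed rows.

    Rows with unparseable timestamps, non-finite values or empty ids are
    excluded from the returned frame and listed in ``rejected`` with their
    1-based file line numbers.  An empty file yields an empty result, not
    an error; a missing required column raises :class:`SchemaError`.
    """
    raw = _read_raw(path, dialect.delimiter)
    if raw.empty and raw.columns.empty:
        return TableReadResult(
            pd.DataFrame(columns=list(MEASUREMENT_COLUMNS)), []
        )
    required = {
        dialect.user_id: "user_id",
        dialect.metric_name: "metric_name",
        dialect.timestamp: "timestamp",
        dialect.value: "value",
    }
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"measurements file is missing column(s): {missing}")

    uid = raw[dialect.user_id].astype(str)
    metric = raw[dialect.metric_name].astype(str)
    ts = pd.to_datetime(raw[dialect.timestamp], errors="coerce", utc=True, format="ISO8601")

    # float() is correctly rounded; pandas' fast csv float path is not,
    # which would break lossless round-trips at the last ulp
    def _to_float(s: str) -> float:
        try:
            return float(s)
        except ValueError:
            return float("nan")

    val = pd.Series([_to_float(s) for s in raw[dialect.value]], index=raw.index, dtype=float)

    ok_ts = ts.notna()
    ok_val = np.isfinite(val.to_numpy(dtype=float, na_value=np.nan))
    ok_id = (uid != "") & (metric != "")
    good = ok_ts & ok_val & ok_id

    rejected: list[RejectedRow] = []
    for i in np.flatnonzero(~good.to_numpy()):
        if not ok_id.iloc[i]:
            reason = "empty user_id or metric_name"
        elif not ok_ts.iloc[i]:
            reason = f"unparseable timestamp {raw[dialect.timestamp].iloc[i]!r}"
        else:
            reason = f"non-finite value {raw[dialect.value].iloc[i]!r}"
        rejected.append(RejectedRow(line_number=int(i) + 2, reason=reason))

    frame = pd.DataFrame(
        {
            "user_id": uid[good].to_numpy(),
            "metric_name": metric[good].to_numpy(),
            "timestamp": ts[good].to_numpy(),
            "value": val[good].to_numpy(dtype=float),
        }
    )
    frame["timestamp"] = pd.to_datetime(frame["timestamp"], utc=True)
    return TableReadResult(frame, rejected)


def write_measurements(frame: pd.DataFrame, path, dialect: Dialect = Dialect()) -> None:
    """Write a measurements frame as delimited text (ISO-8601 timestamps)."""
    out = pd.DataFrame(
        {
            dialect.user_id: frame["user_id"],
            dialect.metric_name: frame["metric_name"],
            dialect.timestamp: [pd.Timestamp(t).isoformat() for t in frame["timestamp"]],
            # repr of a Python float is the shortest string that round-trips
            dialect.value: [repr(float(v)) for v in frame["value"]],
        }
    )
    out.to_csv(path, sep=dialect.delimiter, index=False)


def read_static_profiles(
    path,
    identifier_columns: Sequence[str] = (),
    dialect: Dialect = Dialect(),
) -> "StaticProfileTable":
    """Read the static-attribute table.

    ``identifier_columns`` names the direct identifiers; they are carried
    as flags on the result so downstream rule enforcement can refuse to
    release them.  Duplicate user ids are a schema error (a profile table
    is keyed by user).
    """
    raw = _read_raw(path, dialect.delimiter)
    if raw.empty and raw.columns.empty:
        return StaticProfileTable(pd.DataFrame(columns=["user_id"]), tuple(identifier_columns))
    if dialect.user_id not in raw.columns:
        raise SchemaError(f"profiles file is missing column {dialect.user_id!r}")
    frame = raw.rename(columns={dialect.user_id: "user_id"})
    dupes = frame.loc[frame["user_id"].duplicated(), "user_id"].unique().tolist()
    if dupes:
        raise SchemaError(f"duplicate user_id(s) in profiles: {dupes}")
    unknown = [c for c in identifier_columns if c not in frame.columns]
    if unknown:
        raise SchemaError(f"identifier column(s) not present in profiles: {unknown}")
    # numeric attribute columns come back as strings; convert where possible
    for col in frame.columns:
        if col == "user_id":
            continue
        converted = pd.to_numeric(frame[col], errors="coerce")
        if converted.notna().all() and len(frame):
            frame[col] = converted
    return StaticProfileTable(frame.reset_index(drop=True), tuple(identifier_columns))


@dataclass
class StaticProfileTable:
    """A cohort's static attributes plus the direct-identifier flags."""

    frame: pd.DataFrame
    identifier_columns: tuple[str, ...] = ()

    @property
    def attribute_names(self) -> list[str]:
        return [c for c in self.frame.columns if c != "user_id"]

    def records(self) -> list[StaticProfile]:
        flags = {c: c in self.identifier_columns for c in self.attribute_names}
        return [
            StaticProfile(str(row["user_id"]), {c: row[c] for c in self.attribute_names}, flags)
            for _, row in self.frame.iterrows()
        ]


def write_static_profiles(frame: pd.DataFrame, path, dialect: Dialect = Dialect()) -> None:
    out = frame.rename(columns={"user_id": dialect.user_id})
    out.to_csv(path, sep=dialect.delimiter, index=False)


@dataclass(frozen=True)
class CohortValidation:
    """Report-only structural check of a cohort; never mutates its input."""

    n_measurements: int
    n_profiles: int
    orphan_measurements: int
    orphan_user_ids: tuple[str, ...]
    duplicate_profile_ids: tuple[str, ...]

    @property
    def n_findings(self) -> int:
        return self.orphan_measurements + len(self.duplicate_profile_ids)


def validate_cohort(cohort: Cohort) -> CohortValidation:
    """Check measurement/profile consistency and report (not raise) findings.

    Findings are measurements whose user has no static profile, and
    duplicated profile rows.  The cohort itself is left untouched.
    """
    profile_ids = set(cohort.profiles["user_id"].astype(str))
    meas_ids = cohort.measurements["user_id"].astype(str)
    orphan_mask = ~meas_ids.isin(profile_ids)
    orphan_ids = tuple(sorted(set(meas_ids[orphan_mask])))
    dupes = cohort.profiles["user_id"].astype(str)
    dup_ids = tuple(sorted(set(dupes[dupes.duplicated()])))
    return CohortValidation(
        n_measurements=len(cohort.measurements),
        n_profiles=len(cohort.profiles),
        orphan_measurements=int(orphan_mask.sum()),
        orphan_user_ids=orphan_ids,
        duplicate_profile_ids=dup_ids,
    )


def measurements_to_records(frame: pd.DataFrame) -> list[MeasurementRecord]:
    return [
        MeasurementRecord(str(r.user_id), str(r.metric_name), r.timestamp, float(r.value))
        for r in frame.itertuples(index=False)
    ]


def records_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    records = list(records)
    return pd.DataFrame(
        {
            "user_id": [r.user_id for r in records],
            "metric_name": [r.metric_name for r in records],
            "timestamp": pd.to_datetime([r.timestamp for r in records], utc=True),
            "value": [r.value for r in records],
        }
    )
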