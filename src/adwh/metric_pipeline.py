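"""The metric anonymization pipeline: aggregate, cap, round, verify buckets.

A *metric* turns raw measurements into export-safe values through three
processing steps:

1. **Aggregation** — per user and half-open time window (UTC day, ISO week
   starting Monday, or calendar month): arithmetic mean, median, or the
   most recent value in the window.
2. **Capping (winsorizing)** — aggregates outside ``[cap_low, cap_high]``
   are mapped to the nearest bound, never dropped, so record counts are
   conserved.  Caps may be explicit (e.g. 50–90 bpm for resting heart
   rate) or ``"auto"``, in which case they default to the empirical
   nearest-rank quantiles that trim the lowest and highest
   ``default_tail_fraction`` (2.5% by default) of the sample.
3. **Rounding** — to the nearest multiple of ``rounding_factor`` (ties
   away from zero), collapsing near-unique values into shared buckets.

Before export, every bucket of the resulting histogram must contain at
least ``bucket_threshold`` *distinct users* (counted across all periods:
a user who ever hit the value is one user).  The default threshold is 30.
:func:`adjust` searches for a definition that satisfies the check:
failing edge buckets are absorbed by tightening the corresponding cap one
bucket at a time; failing interior buckets advance the rounding factor
along a schedule; if the schedule is exhausted the aggregation period is
lengthened and the search restarts.  Every step is logged; an exhausted
search reports failure rather than exporting.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

logger = logging.getLogger(__name__)

PERIODS = ("day", "week", "month")
PERIOD_LENGTH_ISO = {"day": "P1D", "week": "P7D", "month": "P1M"}

AUTO = "auto"


@dataclass(frozen=True)
class MetricDefinition:
    """The anonymization recipe for one metric.

    Parameters
    ----------
    aggregation_mode:
        ``mean`` | ``median`` | ``most_recent``.
    period:
        ``day`` | ``week`` (ISO, Monday start) | ``month`` (calendar).
        Windows are half-open ``[start, start + period)`` in UTC.
    cap_low, cap_high:
        Explicit bounds, or ``"auto"`` for nearest-rank quantile caps at
        ``default_tail_fraction`` / ``1 - default_tail_fraction``.
    rounding_factor:
        Bucket width; aggregates are rounded to its nearest multiple.
    bucket_threshold:
        Minimum number of distinct users per bucket for export.
    rounding_schedule:
        Factors the adjustment search may escalate through.
    self_identifying:
        Metrics that identify by nature (e.g. GPS tracks) can never be
        exported regardless of bucketing.
    """

    metric_name: str
    aggregation_mode: str = "mean"
    period: str = "week"
    cap_low: float | str = AUTO
    cap_high: float | str = AUTO
    default_tail_fraction: float = 0.025
    rounding_factor: float = 1.0
    bucket_threshold: int = 30
    self_identifying: bool = False
    rounding_schedule: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0)

    def __post_init__(self) -> None:
        if self.aggregation_mode not in ("mean", "median", "most_recent"):
            raise ConfigError(f"unknown aggregation_mode {self.aggregation_mode!r}")
        if self.period not in PERIODS:
            raise ConfigError(f"unknown period {self.period!r}")
        if not self.rounding_factor > 0:
            raise ConfigError("rounding_factor must be > 0")
        if self.bucket_threshold < 1:
            raise ConfigError("bucket_threshold must be >= 1")
        if not (0 <= self.default_tail_fraction < 0.5):
            raise ConfigError("default_tail_fraction must be in [0, 0.5)")
        explicit_low = not isinstance(self.cap_low, str)
        explicit_high = not isinstance(self.cap_high, str)
        if explicit_low and explicit_high and not self.cap_low < self.cap_high:
            raise ConfigError("cap_low must be < cap_high")
        for cap in (self.cap_low, self.cap_high):
            if isinstance(cap, str) and cap != AUTO:
                raise ConfigError(f"cap must be a number or {AUTO!r}, got {cap!r}")


@dataclass(frozen=True)
class Caps:
    low: float
    high: float


# --------------------------------------------------------------------------
# Aggregation
# --------------------------------------------------------------------------

def period_start(timestamps: pd.Series, period: str) -> pd.Series:
    """Map each timestamp to the start of its half-open UTC window."""
    t = timestamps.dt.tz_convert("UTC")
    day = t.dt.normalize()
    if period == "day":
        return day
    if period == "week":
        return day - pd.to_timedelta(t.dt.weekday, unit="D")
    if period == "month":
        return day - pd.to_timedelta(t.dt.day - 1, unit="D")
    raise ConfigError(f"unknown period {period!r}")


def aggregate(measurements: pd.DataFrame, definition: MetricDefinition) -> pd.DataFrame:
    """Aggregate raw measurements into one value per (user, period).

    Rows whose ``metric_name`` differs from the definition's are ignored.
    Returns a frame with columns ``user_id``, ``period_start`` (tz-aware
    UTC timestamp) and ``raw_aggregate``.
    """
    sub = measurements[measurements["metric_name"] == definition.metric_name]
    if sub.empty:
        return pd.DataFrame(columns=["user_id", "period_start", "raw_aggregate"])
    sub = sub.assign(period_start=period_start(sub["timestamp"], definition.period))
    keys = ["user_id", "period_start"]
    if definition.aggregation_mode == "mean":
        agg = sub.groupby(keys, sort=True)["value"].mean()
    elif definition.aggregation_mode == "median":
        agg = sub.groupby(keys, sort=True)["value"].median()
    else:  # most_recent: value at the max timestamp; later file row wins ties
        ordered = sub.sort_values("timestamp", kind="stable")
        agg = ordered.groupby(keys, sort=True)["value"].last()
    out = agg.rename("raw_aggregate").reset_index()
    return out


# --------------------------------------------------------------------------
# Capping and rounding primitives
# --------------------------------------------------------------------------

def nearest_rank_quantile(sorted_values: np.ndarray, q: float) -> float:
    """Nearest-rank quantile of an ascending array: the value at 1-based
    rank ``ceil(q * n)`` (clamped to [1, n]); exact and convention-free."""
    n = len(sorted_values)
    if n == 0:
        raise ValueError("empty sample")
    rank = min(max(math.ceil(q * n), 1), n)
    return float(sorted_values[rank - 1])


def resolve_caps(aggregates: pd.DataFrame, definition: MetricDefinition) -> Caps:
    """Resolve ``"auto"`` caps into concrete bounds.

    Explicit caps pass through.  Auto caps are the nearest-rank quantiles
    at ``default_tail_fraction`` and its complement, so capping then
    winsorizes (at most) the lowest and highest tail fraction of the
    aggregate sample.  A degenerate all-equal sample yields equal caps
    with a warning rather than an error.
    """
    need_auto = isinstance(definition.cap_low, str) or isinstance(definition.cap_high, str)
    if need_auto and aggregates.empty:
        raise ConfigError("auto caps need a non-empty aggregate sample")
    if need_auto:
        values = np.sort(aggregates["raw_aggregate"].to_numpy(dtype=float))
        t = definition.default_tail_fraction
    low = (
        nearest_rank_quantile(values, t)
        if isinstance(definition.cap_low, str)
        else float(definition.cap_low)
    )
    high = (
        nearest_rank_quantile(values, 1.0 - t)
        if isinstance(definition.cap_high, str)
        else float(definition.cap_high)
    )
    if low > high:
        raise ConfigError(f"resolved caps are inverted: ({low}, {high})")
    if low == high:
        warnings.warn(
            f"degenerate capping range for {definition.metric_name!r}: all "
            f"aggregates collapse to {low}",
            stacklevel=2,
        )
    return Caps(low, high)


def cap_value(x: float, cap_low: float, cap_high: float) -> tuple[float, str]:
    """Winsorize one value; returns (capped, direction in {none, low, high})."""
    if cap_low > cap_high:
        raise ValueError("cap_low must be <= cap_high")
    if x < cap_low:
        return cap_low, "low"
    if x > cap_high:
        return cap_high, "high"
    return x, "none"


def cap_series(values: np.ndarray, caps: Caps) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized winsorizing; returns (capped values, direction labels)."""
    values = np.asarray(values, dtype=float)
    direction = np.where(
        values < caps.low, "low", np.where(values > caps.high, "high", "none")
    )
    return np.clip(values, caps.low, caps.high), direction


def round_value(x: float, rounding_factor: float) -> float:
    """Round to the nearest multiple of ``rounding_factor``; exact halves
    round away from zero (a fixed rule, immune to platform banker's
    rounding)."""
    if not rounding_factor > 0:
        raise ValueError("rounding_factor must be > 0")
    return bucket_index_of(x, rounding_factor) * rounding_factor


def bucket_index_of(x: float, rounding_factor: float) -> int:
    """Signed integer index of the rounding bucket containing ``x``.

    Bucket identity is load-bearing (counts are keyed on it), so keys are
    canonicalized as integer multiples of the factor instead of floats.
    """
    i = math.floor(abs(x) / rounding_factor + 0.5)
    return int(math.copysign(i, x)) if x != 0 else 0


def _bucket_indices(values: np.ndarray, rounding_factor: float) -> np.ndarray:
    i = np.floor(np.abs(values) / rounding_factor + 0.5)
    return (np.sign(values) * i).astype(np.int64)


# --------------------------------------------------------------------------
# Histogram and bucket checks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Bucket:
    value: float
    distinct_user_count: int
    record_count: int
    winsorized_in: int


@dataclass
class BucketHistogram:
    """Distinct-user counts per rounded bucket — the pre-export audit object.

    ``buckets`` is keyed by the canonical integer bucket index
    (``value = index * rounding_factor``) and iterates in ascending order.
    The eligible-user set the histogram was restricted to is retained so
    the export gate can verify the restriction actually happened.
    """

    buckets: dict[int, Bucket]
    rounding_factor: float
    threshold: int
    caps: Caps
    eligible_users: frozenset

    def __post_init__(self) -> None:
        self.buckets = dict(sorted(self.buckets.items()))

    @property
    def n_buckets(self) -> int:
        return len(self.buckets)

    @property
    def total_records(self) -> int:
        return sum(b.record_count for b in self.buckets.values())

    def min_distinct_user_count(self) -> int:
        if not self.buckets:
            return 0
        return min(b.distinct_user_count for b in self.buckets.values())

    def values(self) -> list[float]:
        return [b.value for b in self.buckets.values()]


def build_histogram(
    aggregates: pd.DataFrame,
    definition: MetricDefinition,
    eligible_users: Iterable[str],
    caps: Optional[Caps] = None,
) -> BucketHistogram:
    """Cap and round the aggregates of eligible users and count per bucket.

    ``distinct_user_count`` counts unique users per bucket across *all*
    periods — a user who ever contributed the value counts once.
    ``winsorized_in`` counts the records a cap moved into the bucket.
    """
    eligible = frozenset(str(u) for u in eligible_users)
    sub = aggregates[aggregates["user_id"].astype(str).isin(eligible)]
    if caps is None:
        caps = resolve_caps(sub if not sub.empty else aggregates, definition)
    f = definition.rounding_factor
    if sub.empty:
        return BucketHistogram({}, f, definition.bucket_threshold, caps, eligible)

    values = sub["raw_aggregate"].to_numpy(dtype=float)
    capped, direction = cap_series(values, caps)
    idx = _bucket_indices(capped, f)

    tally = pd.DataFrame(
        {"idx": idx, "user_id": sub["user_id"].to_numpy(), "wins": direction != "none"}
    )
    grouped = tally.groupby("idx", sort=True)
    buckets = {
        int(i): Bucket(
            value=float(i) * f,
            distinct_user_count=int(g["user_id"].nunique()),
            record_count=int(len(g)),
            winsorized_in=int(g["wins"].sum()),
        )
        for i, g in grouped
    }
    return BucketHistogram(buckets, f, definition.bucket_threshold, caps, eligible)


@dataclass(frozen=True)
class FailingBucket:
    value: float
    distinct_user_count: int
    position: str  # "edge" | "interior"


def check_buckets(histogram: BucketHistogram) -> tuple[bool, list[FailingBucket]]:
    """Verify that every bucket has at least ``threshold`` distinct users.

    Failing buckets are tagged ``edge`` (lowest or highest bucket — fixable
    by tightening a cap) or ``interior`` (fixable only by coarser rounding
    or a longer aggregation period).
    """
    if not histogram.buckets:
        return True, []
    indices = list(histogram.buckets)
    lo, hi = indices[0], indices[-1]
    failing = [
        FailingBucket(
            value=b.value,
            distinct_user_count=b.distinct_user_count,
            position="edge" if i in (lo, hi) else "interior",
        )
        for i, b in histogram.buckets.items()
        if b.distinct_user_count < histogram.threshold
    ]
    return not failing, failing


# --------------------------------------------------------------------------
# Histogram masking
# --------------------------------------------------------------------------

def mask_histogram(histogram: BucketHistogram) -> list[dict]:
    """Displayable histogram with sub-threshold counts hidden.

    Even auditors inspecting the histogram before export must not see
    counts that reflect fewer than ``threshold`` users; those buckets show
    a ``"<threshold"`` marker instead of the exact count.
    """
    marker = f"<{histogram.threshold}"
    rows = []
    for b in histogram.buckets.values():
        below = b.distinct_user_count < histogram.threshold
        rows.append(
            {
                "bucket_value": b.value,
                "distinct_user_count": marker if below else b.distinct_user_count,
                "record_count": marker if below else b.record_count,
                "winsorized_in": marker if below else b.winsorized_in,
            }
        )
    return rows


def format_histogram(masked: list[dict], bar_width: int = 50) -> str:
    """Monospace rendering of a masked histogram."""
    if not masked:
        return "(empty histogram)\n"
    counts = [r["distinct_user_count"] for r in masked if isinstance(r["distinct_user_count"], int)]
    peak = max(counts) if counts else 1
    lines = [f"{'bucket':>10}  {'users':>8}  "]
    for r in masked:
        c = r["distinct_user_count"]
        if isinstance(c, int):
            bar = "#" * max(1, round(bar_width * c / peak))
            lines.append(f"{r['bucket_value']:>10g}  {c:>8d}  {bar}")
        else:
            lines.append(f"{r['bucket_value']:>10g}  {c:>8}  (masked)")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Automatic adjustment search
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AdjustmentStep:
    action: str  # tighten_cap_low | tighten_cap_high | increase_rounding | lengthen_period
    old: object
    new: object


@dataclass
class AdjustmentResult:
    final_definition: MetricDefinition
    caps: Caps
    histogram: BucketHistogram
    steps: list[AdjustmentStep]
    satisfied: bool
    aggregates: pd.DataFrame = field(repr=False, default=None)


def _next_factor(current: float, schedule: Sequence[float]) -> Optional[float]:
    for f in schedule:
        if f > current:
            return f
    return None


def _next_period(current: str) -> Optional[str]:
    i = PERIODS.index(current)
    return PERIODS[i + 1] if i + 1 < len(PERIODS) else None


def adjust(
    aggregates: pd.DataFrame,
    definition: MetricDefinition,
    eligible_users: Iterable[str],
    measurements: Optional[pd.DataFrame] = None,
    max_steps: int = 500,
) -> AdjustmentResult:
    """Search for capping/rounding/period parameters that satisfy the
    bucket-threshold check, logging every step.

    Strategy, in priority order per iteration:

    1. A failing **edge** bucket is absorbed by tightening the
       corresponding cap inward one bucket (its records are winsorized
       into the neighbouring bucket).  When both edges fail, the tail with
       the smaller distinct-user count is tightened first; ties go to the
       lower tail.
    2. Failing **interior** buckets advance the rounding factor along the
       schedule.
    3. With the schedule exhausted, the aggregation period is lengthened
       one step (day → week → month) and caps restart from the original
       definition.  This needs the raw ``measurements``; without them the
       search stops at the rounding stage.

    The search never exports on failure: an exhausted search returns
    ``satisfied=False`` with the full step log.
    """
    eligible = frozenset(str(u) for u in eligible_users)
    defn = definition
    caps = resolve_caps(
        aggregates[aggregates["user_id"].astype(str).isin(eligible)]
        if not aggregates.empty else aggregates,
        defn,
    )
    steps: list[AdjustmentStep] = []

    for _ in range(max_steps):
        hist = build_histogram(aggregates, defn, eligible, caps)
        satisfied, failing = check_buckets(hist)
        if satisfied:
            final = replace(defn, cap_low=caps.low, cap_high=caps.high)
            return AdjustmentResult(final, caps, hist, steps, True, aggregates)

        edges = [fb for fb in failing if fb.position == "edge"]
        step = None
        if edges and hist.n_buckets > 1:
            # smaller failing count first; ties -> lower tail
            edges.sort(key=lambda fb: (fb.distinct_user_count, fb.value))
            target = edges[0]
            indices = list(hist.buckets)
            low_value = hist.buckets[indices[0]].value
            high_value = hist.buckets[indices[-1]].value
            f = defn.rounding_factor
            if target.value == low_value and low_value + f < high_value:
                new_caps = Caps(low_value + f, caps.high)
                step = AdjustmentStep("tighten_cap_low", caps.low, new_caps.low)
                caps = new_caps
            elif target.value == high_value and high_value - f > low_value:
                new_caps = Caps(caps.low, high_value - f)
                step = AdjustmentStep("tighten_cap_high", caps.high, new_caps.high)
                caps = new_caps
            # else: tightening would collapse the range; fall through

        if step is None:
            nf = _next_factor(defn.rounding_factor, defn.rounding_schedule)
            if nf is not None:
                step = AdjustmentStep("increase_rounding", defn.rounding_factor, nf)
                defn = replace(defn, rounding_factor=nf)
            else:
                np_ = _next_period(defn.period)
                if np_ is not None and measurements is not None:
                    step = AdjustmentStep("lengthen_period", defn.period, np_)
                    defn = replace(
                        defn,
                        period=np_,
                        rounding_factor=definition.rounding_factor,
                    )
                    aggregates = aggregate(measurements, defn)
                    caps = resolve_caps(
                        aggregates[aggregates["user_id"].astype(str).isin(eligible)],
                        replace(definition, period=np_),
                    )
                else:
                    logger.info("adjustment search exhausted after %d steps", len(steps))
                    final = replace(defn, cap_low=caps.low, cap_high=caps.high)
                    return AdjustmentResult(final, caps, hist, steps, False, aggregates)

        logger.info(
            "adjust[%s]: %s %s -> %s", definition.metric_name, step.action, step.old, step.new
        )
        steps.append(step)

    final = replace(defn, cap_low=caps.low, cap_high=caps.high)
    hist = build_histogram(aggregates, defn, eligible, caps)
    return AdjustmentResult(final, caps, hist, steps, check_buckets(hist)[0], aggregates)
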