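"""The export gate: the only path by which data reaches the warehouse.

Three conditions must all hold before a metric is exported:

1. only users eligible under the static k-anonymity check contribute;
2. the metric is not self-identifying by nature (GPS tracks never leave);
3. every histogram bucket reaches the distinct-user threshold.

When the gate opens, users are replaced by random 128-bit pseudonyms and
each (user, period) aggregate is written as a sanitized row
``anon_id, metric_name, period_start, period_length, bucket_value`` —
capped and rounded, with no raw aggregate, timestamp or original user id
anywhere in the output bytes.  The pseudonym table exists only in memory
(optionally seeded for reproducible test runs); it is never serialized
with the warehouse output, so the warehouse holds no mapping back to
users.  An audit report (decision, masked histogram, adjustment log)
accompanies every export.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import RefusalError
from .metric_pipeline import (
    AdjustmentStep,
    BucketHistogram,
    Caps,
    MetricDefinition,
    PERIOD_LENGTH_ISO,
    _bucket_indices,
    cap_series,
    check_buckets,
    mask_histogram,
    round_value,
)
from .static_anonymizer import AnonymityReport

WAREHOUSE_COLUMNS = ("anon_id", "metric_name", "period_start", "period_length", "bucket_value")


@dataclass(frozen=True)
class ExportDecision:
    """The three-condition verdict for one metric."""

    metric_name: str
    users_eligible_only: bool
    not_self_identifying: bool
    buckets_satisfied: bool
    reasons: tuple[str, ...] = ()

    @property
    def allowed(self) -> bool:
        return (
            self.users_eligible_only
            and self.not_self_identifying
            and self.buckets_satisfied
        )

    def to_json_dict(self) -> dict:
        return {
            "metric_name": self.metric_name,
            "conditions": {
                "users_eligible_only": self.users_eligible_only,
                "not_self_identifying": self.not_self_identifying,
                "buckets_satisfied": self.buckets_satisfied,
            },
            "allowed": self.allowed,
            "reasons": list(self.reasons),
        }


def decide_export(
    definition: MetricDefinition,
    anonymity: AnonymityReport,
    histogram: BucketHistogram,
) -> ExportDecision:
    """Evaluate the three export conditions; never raises on refusal —
    the decision object carries the reasons."""
    reasons = []

    eligible_ok = histogram.eligible_users <= anonymity.eligible_users
    if not eligible_ok:
        extra = len(histogram.eligible_users - anonymity.eligible_users)
        reasons.append(
            f"condition 1: histogram includes {extra} user(s) outside the "
            "k-anonymity eligible set"
        )

    not_self_id = not definition.self_identifying
    if not not_self_id:
        reasons.append(
            f"condition 2: metric {definition.metric_name!r} is self-identifying "
            "by nature and can never be exported"
        )

    satisfied, failing = check_buckets(histogram)
    if not satisfied:
        listed = ", ".join(
            f"{fb.value:g} ({fb.distinct_user_count} users, {fb.position})"
            for fb in failing[:10]
        )
        reasons.append(
            f"condition 3: {len(failing)} bucket(s) below the "
            f"{histogram.threshold}-user threshold: {listed}"
        )

    return ExportDecision(
        metric_name=definition.metric_name,
        users_eligible_only=eligible_ok,
        not_self_identifying=not_self_id,
        buckets_satisfied=satisfied,
        reasons=tuple(reasons),
    )


@dataclass
class PseudonymTable:
    """In-memory user → random-id mapping.

    Injective by construction.  With a seed the mapping is reproducible;
    unseeded runs draw from the system RNG and are unlinkable across
    runs.  Never write this table to the warehouse side.
    """

    mapping: dict
    seed: Optional[int] = None

    def __getitem__(self, user_id: str) -> str:
        return self.mapping[user_id]

    def __len__(self) -> int:
        return len(self.mapping)

    def anon_ids(self) -> set:
        return set(self.mapping.values())


def pseudonymize(users: Iterable[str], seed: Optional[int] = None) -> PseudonymTable:
    """Assign each user a random identifier from a 128-bit space.

    At 128 bits the collision probability for any realistic cohort is
    negligible (birthday bound ~ n²/2¹²⁹), but injectivity is enforced
    anyway.
    """
    rng = random.Random(seed) if seed is not None else random.SystemRandom()
    mapping: dict = {}
    used: set = set()
    for uid in sorted(str(u) for u in users):
        while True:
            anon = f"{rng.getrandbits(128):032x}"
            if anon not in used:
                break
        used.add(anon)
        mapping[uid] = anon
    return PseudonymTable(mapping, seed)


def _fmt_value(x: float) -> str:
    return f"{x:.10g}"


def build_warehouse_frame(
    aggregates: pd.DataFrame,
    definition: MetricDefinition,
    caps: Caps,
    table: PseudonymTable,
    eligible_users: Iterable[str],
) -> pd.DataFrame:
    """Sanitized rows for the warehouse: pseudonymized, capped, rounded.

    One row per (user, period) aggregate of an eligible user.  This is the
    in-memory form shared by file export and the attack simulator.
    """
    eligible = frozenset(str(u) for u in eligible_users)
    sub = aggregates[aggregates["user_id"].astype(str).isin(eligible)]
    if sub.empty:
        return pd.DataFrame(columns=list(WAREHOUSE_COLUMNS))
    capped, _ = cap_series(sub["raw_aggregate"].to_numpy(dtype=float), caps)
    idx = _bucket_indices(capped, definition.rounding_factor)
    values = idx.astype(float) * definition.rounding_factor
    return pd.DataFrame(
        {
            "anon_id": [table[str(u)] for u in sub["user_id"]],
            "metric_name": definition.metric_name,
            "period_start": [pd.Timestamp(t).date().isoformat() for t in sub["period_start"]],
            "period_length": PERIOD_LENGTH_ISO[definition.period],
            "bucket_value": values,
        }
    )


@dataclass
class ExportOutcome:
    records_written: int
    warehouse_path: Optional[Path]
    audit_path: Optional[Path]
    audit: dict


def export(
    aggregates: pd.DataFrame,
    definition: MetricDefinition,
    decision: ExportDecision,
    table: PseudonymTable,
    destination,
    histogram: BucketHistogram,
    adjustment_steps: Sequence[AdjustmentStep] = (),
) -> ExportOutcome:
    """Write warehouse rows and the audit report — only if the decision allows.

    A refused decision raises :class:`RefusalError` before anything is
    written.  Output is fully built in memory first, so an unwritable
    destination fails before any partial file appears.  The audit report
    (JSON, written next to the warehouse file) contains the decision, the
    masked histogram and the adjustment log — nothing at individual-user
    granularity.
    """
    if not decision.allowed:
        raise RefusalError(
            f"export of {definition.metric_name!r} refused: "
            + "; ".join(decision.reasons)
        )

    frame = build_warehouse_frame(
        aggregates, definition, histogram.caps, table, histogram.eligible_users
    )
    frame = frame.copy()
    frame["bucket_value"] = [_fmt_value(v) for v in frame["bucket_value"]]

    audit = {
        "decision": decision.to_json_dict(),
        "definition": {
            "metric_name": definition.metric_name,
            "aggregation_mode": definition.aggregation_mode,
            "period": definition.period,
            # auto caps are nearest-rank quantiles, i.e. one user's exact
            # aggregate; the audit reports them bucket-aligned only
            "cap_low": round_value(histogram.caps.low, definition.rounding_factor),
            "cap_high": round_value(histogram.caps.high, definition.rounding_factor),
            "rounding_factor": definition.rounding_factor,
            "bucket_threshold": definition.bucket_threshold,
        },
        "masked_histogram": mask_histogram(histogram),
        "adjustment_steps": [
            {"action": s.action, "old": s.old, "new": s.new} for s in adjustment_steps
        ],
        "records_written": int(len(frame)),
    }

    destination = Path(destination)
    csv_text = frame.to_csv(index=False)
    audit_text = json.dumps(audit, indent=2, default=str)
    audit_path = destination.with_suffix(destination.suffix + ".audit.json")
    with open(destination, "w", encoding="utf-8") as fh:
        fh.write(csv_text)
    with open(audit_path, "w", encoding="utf-8") as fh:
        fh.write(audit_text)
    return ExportOutcome(len(frame), destination, audit_path, audit)


def export_static_table(
    generalized: pd.DataFrame,
    anonymity: AnonymityReport,
    table: PseudonymTable,
    destination=None,
) -> pd.DataFrame:
    """Optionally release the generalized static attributes, pseudonymized
    and restricted to the k-eligible users — the same gate as metrics.

    Returned (and optionally written) with ``anon_id`` in place of
    ``user_id``; the original ids never appear.
    """
    eligible = generalized["user_id"].astype(str).isin(anonymity.eligible_users)
    sub = generalized[eligible].copy()
    sub.insert(0, "anon_id", [table[str(u)] for u in sub["user_id"]])
    sub = sub.drop(columns=["user_id"])
    if destination is not None:
        sub.to_csv(destination, index=False)
    return sub
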