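"""Suppression, generalization and k-anonymity accounting for static attributes.

A record is k-anonymous when at least k−1 other users share its full tuple
of (generalized) static attributes; k for a cohort is the size of the
smallest equivalence class.  This module applies generalization rules
(suppress a column, bin a numeric column into half-open intervals, map a
categorical column to broader categories), partitions users into
equivalence classes, and produces the anonymity report that downstream
export decisions consume: achieved k, optional distinct-value l-diversity
of a sensitive attribute, the class-size histogram, and the set of users
eligible for export (members of classes of size ≥ k_required).

A hard safety gate: a column flagged as a direct identifier must carry a
suppress rule; otherwise :func:`apply_rules` refuses to run.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .data_model import MISSING_CATEGORY, StaticProfileTable
from .errors import ConfigError, RefusalError


# --------------------------------------------------------------------------
# Generalization rules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Suppress:
    """Drop the attribute entirely from the generalized table."""

    attribute: str


@dataclass(frozen=True)
class NumericBinning:
    """Replace a numeric attribute by the half-open interval containing it.

    Value ``v`` maps to the unique interval ``[origin + i*width,
    origin + (i+1)*width)``, labelled ``"[lo,hi)"``.  Missing values map to
    their own category rather than being merged into a real bin.
    """

    attribute: str
    width: float
    origin: float = 0.0

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ConfigError(f"bin width must be > 0, got {self.width}")


@dataclass(frozen=True)
class CategoricalMap:
    """Replace categorical values by broader categories via a lookup table.

    The mapping must cover every observed value unless ``fallback`` names a
    catch-all category.
    """

    attribute: str
    mapping: Mapping[str, str]
    fallback: Optional[str] = None


GeneralizationRule = Union[Suppress, NumericBinning, CategoricalMap]


def _fmt_bound(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


def bin_index(v: float, width: float, origin: float) -> int:
    """Index of the half-open bin ``[origin + i*width, origin + (i+1)*width)``
    containing ``v``, with floating-point boundary correction so that the
    containment invariant holds exactly for the returned index."""
    i = math.floor((v - origin) / width)
    while v < origin + i * width:
        i -= 1
    while v >= origin + (i + 1) * width:
        i += 1
    return i


def bin_label(v, width: float, origin: float) -> str:
    if pd.isna(v):
        return MISSING_CATEGORY
    i = bin_index(float(v), width, origin)
    lo = origin + i * width
    hi = origin + (i + 1) * width
    return f"[{_fmt_bound(lo)},{_fmt_bound(hi)})"


def apply_rules(
    profiles: StaticProfileTable,
    rules: Sequence[GeneralizationRule],
) -> pd.DataFrame:
    """Apply suppression/generalization rules to a static-attribute table.

    Returns a new frame (``user_id`` plus generalized attribute columns).
    Raises :class:`RefusalError` if any flagged direct identifier lacks a
    suppress rule — the one configuration that must never slip through —
    and :class:`ConfigError` for rules naming unknown attributes or
    categorical maps that do not cover the observed values.
    """
    known = set(profiles.attribute_names)
    for rule in rules:
        if rule.attribute not in known:
            raise ConfigError(f"rule for unknown attribute {rule.attribute!r}")

    suppressed = {r.attribute for r in rules if isinstance(r, Suppress)}
    unprotected = [c for c in profiles.identifier_columns if c not in suppressed]
    if unprotected:
        raise RefusalError(
            "direct identifier(s) without a suppress rule: "
            f"{unprotected}; refusing to generalize"
        )

    out = profiles.frame.copy()
    for rule in rules:
        if isinstance(rule, Suppress):
            out = out.drop(columns=[rule.attribute])
        elif isinstance(rule, NumericBinning):
            col = pd.to_numeric(out[rule.attribute], errors="coerce")
            out[rule.attribute] = [bin_label(v, rule.width, rule.origin) for v in col]
        elif isinstance(rule, CategoricalMap):
            def _map(v, rule=rule):
                if pd.isna(v) or v == "":
                    return MISSING_CATEGORY
                key = str(v)
                if key in rule.mapping:
                    return rule.mapping[key]
                if rule.fallback is not None:
                    return rule.fallback
                raise ConfigError(
                    f"categorical map for {rule.attribute!r} does not cover "
                    f"value {key!r} and declares no fallback"
                )
            out[rule.attribute] = [_map(v) for v in out[rule.attribute]]
        else:  # pragma: no cover - exhaustive over the union
            raise ConfigError(f"unknown rule type {type(rule).__name__}")

    # missing values in untouched columns still form their own category
    for col in out.columns:
        if col == "user_id":
            continue
        if out[col].isna().any():
            out[col] = out[col].astype(object).where(out[col].notna(), MISSING_CATEGORY)
    return out


# --------------------------------------------------------------------------
# Equivalence classes and the anonymity report
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EquivalenceClass:
    """Users identical on every generalized quasi-identifier value."""

    key: tuple
    members: frozenset
    sensitive_values: tuple = ()

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def distinct_sensitive(self) -> int:
        return len(set(self.sensitive_values))


def equivalence_classes(
    generalized: pd.DataFrame,
    sensitive_attribute: Optional[str] = None,
) -> list[EquivalenceClass]:
    """Partition users by their full generalized attribute tuple.

    The sensitive attribute, when designated, is held out of the class key
    and collected as the class's multiset of sensitive values.  Classes are
    returned in deterministic order (sorted by stringified key).
    """
    key_cols = [
        c for c in generalized.columns if c != "user_id" and c != sensitive_attribute
    ]
    if sensitive_attribute is not None and sensitive_attribute not in generalized.columns:
        raise ConfigError(f"sensitive attribute {sensitive_attribute!r} not in table")

    if not key_cols:
        members = frozenset(generalized["user_id"].astype(str))
        sens = (
            tuple(generalized[sensitive_attribute]) if sensitive_attribute else ()
        )
        return [EquivalenceClass((), members, sens)]

    classes = []
    grouped = generalized.groupby(key_cols, dropna=False, sort=False)
    for key, sub in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        sens = tuple(sub[sensitive_attribute]) if sensitive_attribute else ()
        classes.append(
            EquivalenceClass(tuple(key), frozenset(sub["user_id"].astype(str)), sens)
        )
    classes.sort(key=lambda c: tuple(str(v) for v in c.key))
    return classes


@dataclass
class AnonymityReport:
    """Cohort-level anonymity accounting.

    ``k_achieved`` is the smallest equivalence-class size; users in classes
    smaller than ``k_required`` are excluded from ``eligible_users``.
    ``l_achieved`` (distinct-value l-diversity) is reported only when a
    sensitive attribute was designated; classes where every member shares
    one sensitive value are vulnerable to a homogeneity attack and counted
    in ``homogeneous_classes``.
    """

    k_required: int
    k_achieved: int
    class_sizes: dict  # size -> number of classes
    eligible_users: frozenset
    n_users: int
    l_achieved: Optional[int] = None
    homogeneous_classes: int = 0

    @property
    def n_eligible(self) -> int:
        return len(self.eligible_users)

    def to_json_dict(self) -> dict:
        """JSON view for audit output.

        Deliberately omits class keys: a small class's key tuple could
        itself single out its members, the same reason sub-threshold
        histogram buckets are masked.
        """
        d = {
            "k_required": self.k_required,
            "k_achieved": self.k_achieved,
            "class_size_histogram": {str(k): v for k, v in sorted(self.class_sizes.items())},
            "n_users": self.n_users,
            "n_eligible_users": self.n_eligible,
        }
        if self.l_achieved is not None:
            d["l_achieved"] = self.l_achieved
            d["homogeneity_vulnerable_classes"] = self.homogeneous_classes
        return d


def anonymity_report(
    classes: Sequence[EquivalenceClass],
    k_required: int,
    sensitive_attribute: Optional[str] = None,
) -> AnonymityReport:
    """Summarize a partition into the anonymity report used by the export gate."""
    if k_required < 1:
        raise ConfigError(f"k_required must be >= 1, got {k_required}")
    if not classes:
        raise ConfigError("cannot build an anonymity report from zero classes")

    sizes = [c.size for c in classes]
    eligible: set = set()
    for c in classes:
        if c.size >= k_required:
            eligible.update(c.members)

    l_achieved = None
    homogeneous = 0
    if sensitive_attribute is not None:
        l_achieved = min(c.distinct_sensitive for c in classes)
        homogeneous = sum(1 for c in classes if c.distinct_sensitive == 1)

    return AnonymityReport(
        k_required=k_required,
        k_achieved=min(sizes),
        class_sizes=dict(Counter(sizes)),
        eligible_users=frozenset(eligible),
        n_users=sum(sizes),
        l_achieved=l_achieved,
        homogeneous_classes=homogeneous,
    )


def anonymize_static(
    profiles: StaticProfileTable,
    rules: Sequence[GeneralizationRule],
    k_required: int = 10,
    sensitive_attribute: Optional[str] = None,
) -> tuple[pd.DataFrame, AnonymityReport]:
    """Convenience pipeline: apply rules, partition, report.

    The default ``k_required`` of 10 reflects the framework's guidance that
    minimum group sizes should be at least double-digit.
    """
    generalized = apply_rules(profiles, rules)
    classes = equivalence_classes(generalized, sensitive_attribute)
    report = anonymity_report(classes, k_required, sensitive_attribute)
    return generalized, report
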