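"""YAML configuration: metric definitions and static generalization rules.

Example::

    identifier_columns: [name]
    k_required: 10
    sensitive_attribute: null
    static_rules:
      - {attribute: name, kind: suppress}
      - {attribute: age, kind: numeric-binning, width: 10, origin: 0}
      - {attribute: country, kind: categorical-map,
         mapping: {CH: DACH, DE: DACH, AT: DACH}, fallback: other}
    metrics:
      - metric_name: resting_heart_rate
        aggregation_mode: mean
        period: week
        cap_low: auto
        cap_high: auto
        default_tail_fraction: 0.025
        rounding_factor: 1
        bucket_threshold: 30
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import yaml

from .errors import ConfigError
from .metric_pipeline import MetricDefinition
from .static_anonymizer import (
    CategoricalMap,
    GeneralizationRule,
    NumericBinning,
    Suppress,
)


@dataclass
class RunConfig:
    metrics: list[MetricDefinition] = field(default_factory=list)
    static_rules: list[GeneralizationRule] = field(default_factory=list)
    identifier_columns: tuple[str, ...] = ()
    k_required: int = 10
    sensitive_attribute: Optional[str] = None

    def metric(self, name: str) -> MetricDefinition:
        for m in self.metrics:
            if m.metric_name == name:
                return m
        raise ConfigError(f"no metric named {name!r} in config")


def _parse_rule(raw: dict) -> GeneralizationRule:
    kind = raw.get("kind")
    attr = raw.get("attribute")
    if attr is None:
        raise ConfigError(f"rule missing 'attribute': {raw}")
    if kind == "suppress":
        return Suppress(attr)
    if kind == "numeric-binning":
        if "width" not in raw:
            raise ConfigError(f"numeric-binning rule needs 'width': {raw}")
        return NumericBinning(attr, float(raw["width"]), float(raw.get("origin", 0.0)))
    if kind == "categorical-map":
        return CategoricalMap(
            attr,
            {str(k): str(v) for k, v in (raw.get("mapping") or {}).items()},
            raw.get("fallback"),
        )
    raise ConfigError(f"unknown rule kind {kind!r}")


def _parse_metric(raw: dict) -> MetricDefinition:
    if "metric_name" not in raw:
        raise ConfigError(f"metric entry missing 'metric_name': {raw}")
    kwargs = dict(raw)
    if "rounding_schedule" in kwargs:
        kwargs["rounding_schedule"] = tuple(float(x) for x in kwargs["rounding_schedule"])
    try:
        return MetricDefinition(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"bad metric definition {raw.get('metric_name')!r}: {exc}") from exc


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return RunConfig(
        metrics=[_parse_metric(m) for m in raw.get("metrics", [])],
        static_rules=[_parse_rule(r) for r in raw.get("static_rules", [])],
        identifier_columns=tuple(raw.get("identifier_columns", [])),
        k_required=int(raw.get("k_required", 10)),
        sensitive_attribute=raw.get("sensitive_attribute"),
    )
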