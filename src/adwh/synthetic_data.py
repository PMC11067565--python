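"""Synthetic identified wearable cohorts for exercising the whole pipeline.

The generator emulates the statistical structure the anonymization
framework assumes about consumer-wearable data: each user carries a
latent trait level (a per-user mean drawn from a between-user normal),
observations scatter around it with within-user noise, measurement counts
per day are Poisson, and a small fraction of users are outliers whose
latent mean is shifted by ±3 between-user standard deviations — these are
the users the capping step exists for.  Static attributes (the
quasi-identifier surface) are drawn independently per user.

Everything is reproducible under a seed, and the default preset —
10,000 users, one ISO week of resting heart rate sampled a few times a
day — is the cohort scale at which per-bucket user thresholds in the
tens are realistically satisfiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .data_model import Cohort
from .errors import ConfigError


@dataclass(frozen=True)
class MetricModel:
    """Gaussian random-intercept model for one measured metric.

    ``baseline_mean`` ± ``between_user_sd`` sets the population spread of
    per-user latent means; ``within_user_sd`` the measurement scatter
    around a user's own mean.
    """

    baseline_mean: float
    between_user_sd: float
    within_user_sd: float

    def __post_init__(self) -> None:
        if self.between_user_sd < 0 or self.within_user_sd < 0:
            raise ConfigError("standard deviations must be >= 0")


@dataclass(frozen=True)
class CategoricalAttribute:
    categories: tuple[str, ...]
    weights: Optional[tuple[float, ...]] = None


@dataclass(frozen=True)
class NumericAttribute:
    low: float
    high: float
    integer: bool = True


AttributeSpec = Union[CategoricalAttribute, NumericAttribute]


def _default_metrics() -> dict:
    # resting heart rate: weekly means land mostly inside 50-90 bpm
    return {"resting_heart_rate": MetricModel(65.0, 8.0, 3.0)}


def _default_statics() -> dict:
    return {
        "sex": CategoricalAttribute(("female", "male")),
        "age": NumericAttribute(18, 80, integer=True),
        "country": CategoricalAttribute(("CH", "DE", "FR", "IT", "AT")),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic identified cohort.

    ``measurements_per_day`` is the Poisson mean of daily observation
    counts; users who would end a week with zero observations get one
    forced measurement so every user has a defined weekly aggregate.
    ``outlier_fraction`` of users have their latent mean shifted by
    ±3 between-user sd (sign random).  ``include_name_identifier`` adds a
    synthetic ``name`` column flagged as a direct identifier so the
    suppression safety gate is exercised end to end.
    """

    n_users: int = 10_000
    weeks: int = 1
    measurements_per_day: float = 4.0
    metrics: Mapping[str, MetricModel] = field(default_factory=_default_metrics)
    outlier_fraction: float = 0.01
    static_attributes: Mapping[str, AttributeSpec] = field(default_factory=_default_statics)
    include_name_identifier: bool = True
    start_date: str = "2024-01-01"  # a Monday: weeks align with ISO weeks
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 1:
            raise ConfigError("n_users must be >= 1")
        if self.weeks < 1:
            raise ConfigError("weeks must be >= 1")
        if not (0 <= self.outlier_fraction < 1):
            raise ConfigError("outlier_fraction must be in [0, 1)")
        if self.measurements_per_day < 0:
            raise ConfigError("measurements_per_day must be >= 0")
        if pd.Timestamp(self.start_date).weekday() != 0:
            raise ConfigError("start_date must be a Monday so weeks are ISO-aligned")


def _user_ids(n: int) -> np.ndarray:
    width = max(5, len(str(n)))
    return np.array([f"u{i:0{width}d}" for i in range(1, n + 1)])


def generate(spec: CohortSpec) -> Cohort:
    """Draw a full identified cohort (profiles + measurements) from a spec.

    Deterministic under ``spec.seed``: the same spec yields byte-identical
    tables.
    """
    rng = np.random.default_rng(spec.seed)
    users = _user_ids(spec.n_users)
    n_days = spec.weeks * 7
    day0 = pd.Timestamp(spec.start_date, tz="UTC")

    # --- static profiles -------------------------------------------------
    profile: dict = {"user_id": users}
    if spec.include_name_identifier:
        profile["name"] = np.array([f"Person {i:05d}" for i in range(1, spec.n_users + 1)])
    for attr, aspec in spec.static_attributes.items():
        if isinstance(aspec, CategoricalAttribute):
            p = None
            if aspec.weights is not None:
                w = np.asarray(aspec.weights, dtype=float)
                p = w / w.sum()
            profile[attr] = rng.choice(aspec.categories, size=spec.n_users, p=p)
        elif isinstance(aspec, NumericAttribute):
            draws = rng.uniform(aspec.low, aspec.high, size=spec.n_users)
            profile[attr] = np.floor(draws).astype(int) if aspec.integer else draws
        else:
            raise ConfigError(f"unknown attribute spec for {attr!r}")
    profiles = pd.DataFrame(profile)

    # --- measurements ----------------------------------------------------
    frames = []
    n_out = int(round(spec.outlier_fraction * spec.n_users))
    for metric_name, model in spec.metrics.items():
        latent = rng.normal(model.baseline_mean, model.between_user_sd, size=spec.n_users)
        if n_out:
            which = rng.choice(spec.n_users, size=n_out, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_out)
            latent[which] += signs * 3.0 * model.between_user_sd

        counts = rng.poisson(spec.measurements_per_day, size=(spec.n_users, n_days))
        # every user must have >= 1 measurement per week (aggregate defined)
        for w in range(spec.weeks):
            week = counts[:, w * 7 : (w + 1) * 7]
            empty = week.sum(axis=1) == 0
            counts[empty, w * 7] = 1

        per_user = counts.sum(axis=1)
        total = int(per_user.sum())
        uid = np.repeat(users, per_user)
        user_latent = np.repeat(latent, per_user)
        day_idx = np.repeat(
            np.tile(np.arange(n_days), spec.n_users), counts.reshape(-1)
        )
        seconds = rng.integers(0, 86_400, size=total)
        ts = day0 + pd.to_timedelta(day_idx * 86_400 + seconds, unit="s")
        values = rng.normal(user_latent, model.within_user_sd)
        frames.append(
            pd.DataFrame(
                {
                    "user_id": uid,
                    "metric_name": metric_name,
                    "timestamp": ts,
                    "value": values,
                }
            )
        )

    measurements = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["user_id", "metric_name", "timestamp"], kind="stable")
        .reset_index(drop=True)
    )
    identifier_columns = ("name",) if spec.include_name_identifier else ()
    return Cohort(profiles, measurements, identifier_columns)


def preset_cohort(seed: int = 0, n_users: int = 10_000) -> Cohort:
    """The reference simulation setting: ``n_users`` (default 10,000) users,
    one ISO week of resting heart rate (~4 measurements/day), default
    static attributes.  Weekly mean aggregation of this cohort is the
    worked example the bucket-threshold machinery is demonstrated on."""
    return generate(CohortSpec(n_users=n_users, weeks=1, seed=seed))
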