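"""Monte-Carlo re-identification attacks against an exported warehouse.

The threat model is the background-knowledge attacker: someone who knows
a target person, knows the person's data is in the warehouse, may know
the person's raw metric values for a specific period (and that the
aggregation is, say, weekly), may know the person's generalized static
attributes, and has read access to the warehouse — but not to the
in-memory pseudonym table.  Each trial picks a random target, computes
the candidate set of warehouse pseudonyms consistent with everything the
attacker knows, and scores a success when the candidate set is exactly
the target alone.  The report gives the empirical success rate with an
exact (Clopper–Pearson) binomial confidence interval plus candidate-set
size statistics; a sweep over metric definitions traces the
risk–utility trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .data_model import Cohort
from .errors import AdwhError, ConfigError
from .export_engine import (
    PseudonymTable,
    build_warehouse_frame,
    decide_export,
    pseudonymize,
)
from .metric_pipeline import (
    MetricDefinition,
    _bucket_indices,
    adjust,
    aggregate,
    cap_series,
)
from .static_anonymizer import GeneralizationRule, anonymize_static


@dataclass(frozen=True)
class AttackerModel:
    """What the attacker knows, and how many trials to run.

    ``known_static`` names generalized attributes the attacker can match
    against a released static table; ``metric_noise_sd`` widens the
    attacker's believed metric value into a ± band (0 = exact knowledge,
    the paper-style scenario).  Without ``knows_aggregation_mode`` the
    raw values are useless and the metric does not constrain candidates.
    """

    known_static: tuple[str, ...] = ()
    knows_metric_value: bool = True
    metric_noise_sd: float = 0.0
    knows_aggregation_mode: bool = True
    n_trials: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        if self.metric_noise_sd < 0:
            raise ConfigError("metric_noise_sd must be >= 0")


@dataclass
class RiskReport:
    n_trials: int
    successes: int
    success_rate: float
    ci_low: float
    ci_high: float
    mean_candidates: float
    min_candidates: int

    def to_json_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "successes": self.successes,
            "success_rate": self.success_rate,
            "ci95": [self.ci_low, self.ci_high],
            "mean_candidate_set_size": self.mean_candidates,
            "min_candidate_set_size": self.min_candidates,
        }


def simulate_attack(
    cohort: Cohort,
    warehouse: pd.DataFrame,
    generalized_profiles: pd.DataFrame,
    model: AttackerModel,
    pseudonyms: PseudonymTable,
    definition: MetricDefinition,
) -> RiskReport:
    """Run ``model.n_trials`` background-knowledge attacks.

    ``warehouse`` must have been produced from ``cohort`` through the
    export engine with ``pseudonyms``; the pseudonym table is used only
    to score success and to build the attacker-visible static table —
    candidate matching itself sees nothing but released data.
    """
    wh_ids = set(warehouse["anon_id"])
    if not wh_ids <= pseudonyms.anon_ids():
        raise AdwhError("warehouse contains pseudonyms not issued for this cohort")

    # ground truth: which users are in the warehouse, under which pseudonym
    reverse = {a: u for u, a in pseudonyms.mapping.items()}
    exported_users = sorted(reverse[a] for a in wh_ids)
    if not exported_users:
        raise AdwhError("warehouse is empty; nothing to attack")

    # the warehouse view the attacker queries
    wh_period = warehouse["period_start"].to_numpy()
    wh_value = warehouse["bucket_value"].to_numpy(dtype=float)
    wh_anon = warehouse["anon_id"].to_numpy()
    all_anon_ids = frozenset(wh_anon)

    # target-side ground truth: each exported (user, period) bucket value,
    # recomputed exactly as the pipeline computed it
    agg = aggregate(cohort.measurements, definition)
    if isinstance(definition.cap_low, str) or isinstance(definition.cap_high, str):
        raise ConfigError("simulate_attack needs a definition with resolved caps")
    from .metric_pipeline import Caps  # local import to avoid cycle noise

    caps = Caps(float(definition.cap_low), float(definition.cap_high))
    capped, _ = cap_series(agg["raw_aggregate"].to_numpy(dtype=float), caps)
    agg = agg.assign(
        bucket_value=_bucket_indices(capped, definition.rounding_factor).astype(float)
        * definition.rounding_factor,
        period_key=[pd.Timestamp(t).date().isoformat() for t in agg["period_start"]],
    )
    target_rows = {
        u: g[["period_key", "bucket_value"]].to_numpy()
        for u, g in agg.groupby("user_id", sort=False)
    }

    # the released static table (attacker-visible), keyed by anon_id
    static_by_anon = None
    if model.known_static:
        missing = [a for a in model.known_static if a not in generalized_profiles.columns]
        if missing:
            raise ConfigError(f"known_static names absent attributes: {missing}")
        gp = generalized_profiles.set_index(generalized_profiles["user_id"].astype(str))
        static_by_anon = pd.DataFrame(
            {
                "anon_id": [pseudonyms[u] for u in exported_users],
                **{
                    a: [gp.at[u, a] for u in exported_users]
                    for a in model.known_static
                },
            }
        )

    rng = np.random.default_rng(model.seed)
    tol = model.metric_noise_sd + 1e-9
    successes = 0
    sizes = []
    for _ in range(model.n_trials):
        target = exported_users[rng.integers(len(exported_users))]
        candidates = all_anon_ids

        if model.knows_metric_value and model.knows_aggregation_mode:
            rows = target_rows.get(target)
            pick = rows[rng.integers(len(rows))]
            period, believed = pick[0], float(pick[1])
            mask = (wh_period == period) & (np.abs(wh_value - believed) <= tol)
            candidates = candidates & set(wh_anon[mask])

        if static_by_anon is not None:
            m = np.ones(len(static_by_anon), dtype=bool)
            target_vals = {
                a: static_by_anon.loc[
                    static_by_anon["anon_id"] == pseudonyms[target], a
                ].iloc[0]
                for a in model.known_static
            }
            for a in model.known_static:
                m &= (static_by_anon[a] == target_vals[a]).to_numpy()
            candidates = candidates & set(static_by_anon.loc[m, "anon_id"])

        sizes.append(len(candidates))
        if len(candidates) == 1 and next(iter(candidates)) == pseudonyms[target]:
            successes += 1

    ci = binomtest(successes, model.n_trials).proportion_ci(
        confidence_level=0.95, method="exact"
    )
    return RiskReport(
        n_trials=model.n_trials,
        successes=successes,
        success_rate=successes / model.n_trials,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        mean_candidates=float(np.mean(sizes)),
        min_candidates=int(np.min(sizes)),
    )


def risk_curve(
    cohort: Cohort,
    definitions: Sequence[MetricDefinition],
    model: AttackerModel,
    rules: Sequence[GeneralizationRule],
    k_required: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Sweep metric definitions through the full pipeline and attack each
    resulting warehouse with identical seeds.

    Output rows are sorted by (bucket_threshold, rounding_factor); a
    definition whose export is refused is marked not-exportable rather
    than being scored as zero risk.
    """
    from .data_model import StaticProfileTable

    profiles = StaticProfileTable(cohort.profiles, cohort.identifier_columns)
    generalized, anonymity = anonymize_static(profiles, rules, k_required)

    rows = []
    for definition in definitions:
        agg = aggregate(cohort.measurements, definition)
        result = adjust(
            agg, definition, anonymity.eligible_users, measurements=cohort.measurements
        )
        decision = decide_export(result.final_definition, anonymity, result.histogram)
        row = {
            "bucket_threshold": definition.bucket_threshold,
            "rounding_factor": definition.rounding_factor,
            "final_rounding_factor": result.final_definition.rounding_factor,
            "exportable": decision.allowed,
            "success_rate": np.nan,
            "mean_candidate_set_size": np.nan,
        }
        if decision.allowed:
            table = pseudonymize(result.histogram.eligible_users, seed=seed)
            warehouse = build_warehouse_frame(
                result.aggregates,
                result.final_definition,
                result.caps,
                table,
                result.histogram.eligible_users,
            )
            report = simulate_attack(
                cohort, warehouse, generalized, model, table, result.final_definition
            )
            row["success_rate"] = report.success_rate
            row["mean_candidate_set_size"] = report.mean_candidates
        rows.append(row)

    return (
        pd.DataFrame(rows)
        .sort_values(["bucket_threshold", "rounding_factor"], kind="stable")
        .reset_index(drop=True)
    )
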