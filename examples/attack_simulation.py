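"""Estimate re-identification risk with Monte-Carlo background-knowledge attacks.

The attacker knows a target's exact raw heart-rate values for a week
(and that aggregation is weekly), optionally plus the target's
generalized static attributes, and queries the exported warehouse for
pseudonyms consistent with that knowledge.  A trial succeeds only when a
single candidate remains and it is the target.  The sweep shows how the
per-bucket user threshold drives the risk down.
"""

from adwh import (
    AttackerModel,
    CohortSpec,
    MetricDefinition,
    NumericBinning,
    Suppress,
    generate,
    risk_curve,
)

cohort = generate(CohortSpec(n_users=2_000, seed=11))
rules = [Suppress("name"), NumericBinning("age", 10, 0)]

definitions = [
    MetricDefinition(
        "resting_heart_rate", bucket_threshold=t, rounding_factor=0.01,
        rounding_schedule=(0.01, 0.1, 1.0, 2.0, 5.0, 10.0),
    )
    for t in (1, 10, 30)
]
model = AttackerModel(known_static=("sex", "age"), n_trials=300, seed=11)

table = risk_curve(cohort, definitions, model, rules, k_required=10, seed=11)
print(table.to_string(index=False))
# success_rate is the fraction of simulated attacks that pinned the target
# uniquely.  With threshold 1 and centi-bpm buckets most weekly means are
# unique and the attacker usually wins; at 30 users per bucket the
# candidate set can never shrink to one on the metric alone, and the rate
# collapses toward zero.
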