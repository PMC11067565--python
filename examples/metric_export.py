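"""The full metric pipeline: aggregate, cap, round, verify, export.

Takes weekly mean resting heart rates of 2,000 users, requires every
rounded-value bucket to hold at least 30 distinct users, lets the
automatic adjustment search find the capping/rounding that achieves it,
and writes the pseudonymized warehouse file plus its audit report.
"""

import tempfile
from pathlib import Path

from adwh import (
    CohortSpec,
    MetricDefinition,
    NumericBinning,
    StaticProfileTable,
    Suppress,
    adjust,
    aggregate,
    anonymize_static,
    decide_export,
    export,
    format_histogram,
    generate,
    mask_histogram,
    pseudonymize,
)

cohort = generate(CohortSpec(n_users=2_000, seed=11))
profiles = StaticProfileTable(cohort.profiles, cohort.identifier_columns)
rules = [Suppress("name"), NumericBinning("age", 10, 0)]
_, anonymity = anonymize_static(profiles, rules, k_required=10)

definition = MetricDefinition("resting_heart_rate", bucket_threshold=30)
weekly = aggregate(cohort.measurements, definition)
result = adjust(weekly, definition, anonymity.eligible_users,
                measurements=cohort.measurements)

print(f"adjustment satisfied: {result.satisfied}")
for step in result.steps:
    print(f"  {step.action}: {step.old} -> {step.new}")
print(f"final rounding factor: {result.final_definition.rounding_factor}")
print(f"capping range: [{result.caps.low:.1f}, {result.caps.high:.1f}] bpm")
print(f"min users per bucket: {result.histogram.min_distinct_user_count()}")
print(format_histogram(mask_histogram(result.histogram)))

decision = decide_export(result.final_definition, anonymity, result.histogram)
print(f"export allowed: {decision.allowed}")

with tempfile.TemporaryDirectory() as tmp:
    table = pseudonymize(result.histogram.eligible_users, seed=11)
    outcome = export(result.aggregates, result.final_definition, decision,
                     table, Path(tmp) / "resting_heart_rate.csv",
                     result.histogram, result.steps)
    print(f"warehouse rows written: {outcome.records_written}")
# Each exported row is (random id, metric, week, P7D, bucketed bpm value):
# nothing finer-grained than a value shared by >= 30 users ever leaves.
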