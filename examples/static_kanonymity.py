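"""Suppress identifiers, generalize the rest, and measure k-anonymity.

Applies the standard rule set (drop the name, bin age by decade) to a
synthetic cohort's static attributes and prints the achieved k — the size
of the smallest group of users sharing identical generalized attributes —
and how many users clear a required minimum group size of 10.
"""

import json

from adwh import (
    CohortSpec,
    NumericBinning,
    StaticProfileTable,
    Suppress,
    anonymize_static,
    generate,
)

cohort = generate(CohortSpec(n_users=2_000, seed=11))
profiles = StaticProfileTable(cohort.profiles, cohort.identifier_columns)

rules = [Suppress("name"), NumericBinning("age", 10, 0)]
generalized, report = anonymize_static(profiles, rules, k_required=10)

print(json.dumps(report.to_json_dict(), indent=2))
# k_achieved is the smallest equivalence class after generalization.
# Users in classes below k_required=10 are *not* eligible for export:
# releasing them would let an attacker who knows a person's sex, age
# decade and country narrow the candidates to fewer than 10 people.
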