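# Methods

`adwh` sanitizes identified digital-health time series for release into a
separate "anonymous data warehouse". This note records the model the
toolkit implements, the parameters that matter, the numerical conventions
it fixes, and what its synthetic cohorts do and do not demonstrate.

## The anonymization model

**Static attributes.** A user's time-invariant attributes (sex, age,
country, ...) are the quasi-identifier surface. Direct identifiers must be
suppressed; remaining attributes may be generalized — numeric values into
half-open intervals `[origin + i·w, origin + (i+1)·w)`, categoricals via a
user-supplied coarsening table. Users are partitioned into equivalence
classes by their full generalized tuple; the cohort's k-anonymity level is
the smallest class size, and only members of classes of size ≥
`k_required` are eligible for export. The default `k_required` is 10:
minimum group sizes below double digits leave too much residual
re-identification and homogeneity-attack risk for health data.
When a sensitive attribute is designated, distinct-value l-diversity is
reported alongside k, and classes whose members all share one sensitive
value are counted as homogeneity-vulnerable. Distinct-count l-diversity is
the only variant implemented; entropy variants and t-closeness are out of
scope, as is any search for a minimal-information-loss generalization —
rules are applied exactly as configured.

**Metrics.** Raw measurements never leave. A metric is defined by three
processing steps, applied per user:

1. *Aggregation* over half-open UTC windows — day, ISO week (Monday
   start) or calendar month — by arithmetic mean, median, or most recent
   value. Naive timestamps are taken as UTC so window assignment is
   machine-independent.
2. *Capping (winsorizing)*: aggregates below `cap_low` or above
   `cap_high` are mapped to the bound, never dropped, so record counts are
   conserved. Caps may be explicit (the worked example for resting heart
   rate uses 50–90 bpm) or `auto`, which resolves to the empirical
   quantiles trimming `default_tail_fraction` (default 2.5%) off each
   tail.
3. *Rounding* to the nearest multiple of `rounding_factor` (default 1).

Before export, every bucket of rounded values must contain at least
`bucket_threshold` **distinct users** (default 30), counted across all
periods: a user who ever produced the value counts once. Three conditions
gate the export: only k-eligible users contribute; the metric is not
self-identifying by nature (GPS tracks and the like are flagged in the
definition and can never pass); and the bucket check holds. The warehouse
row is `(anon_id, metric_name, period_start, period_length,
bucket_value)` — pseudonym, week, bucketed value, nothing else.

## Numerical conventions

These are fixed so that two runs of the pipeline on the same data can
never disagree about a bucket:

- **Rounding tie rule**: exact halves round away from zero. Platform
  banker's rounding would make bucket membership depend on the libm in
  use.
- **Bucket identity**: bucket keys are canonical integer multiples of the
  rounding factor (`index = round(x / f)` as an int), not floats, so
  equality never drifts.
- **Auto-cap quantiles**: nearest rank on the sorted sample — the value at
  1-based rank `ceil(q·n)`. This is exact and convention-free, at the cost
  that the realized winsorized fraction is within one rank of the nominal
  tail (249/10,000 = 2.49% rather than 2.50% at the lower tail of a
  continuous sample of 10,000).
- **Degenerate inputs**: an all-equal aggregate sample under auto caps
  yields equal caps with a warning (one bucket, not an error); an empty
  eligible set yields an empty histogram which trivially satisfies the
  bucket check but exports zero rows; missing attribute values generalize
  to their own `∅` category rather than merging into a real bin, which
  could otherwise fabricate homogeneous classes.
- **Binning boundary correction**: the bin index starts from
  `floor((v − origin)/w)` and is nudged until the half-open containment
  invariant holds exactly, so a value on a float-noisy boundary always
  lands in the interval whose printed label contains it.

## The adjustment search

When the bucket check fails, parameters are escalated in a fixed priority
order, one step per iteration, every step logged:

1. **Failing edge buckets** → tighten the corresponding cap inward one
   bucket; the displaced records are winsorized into the neighbour. This
   only ever *raises* bucket counts (the edge bucket's users merge
   inward), so the minimum distinct-user count is monotone along this
   move. When both edges fail, the tail with the smaller count goes
   first; ties go to the lower tail.
2. **Failing interior buckets** → advance the rounding factor along the
   schedule (default 1, 2, 5, 10).
3. **Schedule exhausted** → lengthen the period one step
   (day → week → month), reset caps and rounding, and restart. This
   requires the raw measurements; `adjust` takes them as an optional
   argument because re-aggregation cannot be derived from the aggregates
   themselves. Without them the search stops after the rounding stage.

An exhausted search returns `satisfied=False` with the full log; nothing
is exported. The number of buckets is not strictly monotone in the
rounding factor in full generality (coarse bucket boundaries do not nest
inside fine ones, so two values sharing a fine bucket can straddle a
coarse boundary); over ranges many buckets wide — the regime the search
operates in — coarsening merges buckets, which is what the escalation
relies on and what the tests exercise.

The bucket check runs per export batch. Checking cumulatively over the
warehouse's lifetime (a user's bucket could fall below threshold relative
to all data ever exported) is noted as future work.

## Pseudonymization and the one-way property

Users are mapped to 128-bit random hex identifiers. The table lives only
in memory; seeding it is supported for reproducible tests, and the seed
is never part of any output. The audit report accompanying an export
contains the decision, the adjustment log and the *masked* histogram —
buckets below threshold show `"<30"` rather than a count, so even
auditors never see single-user granularity. Resolved auto caps are
reported bucket-aligned in the audit, because a nearest-rank quantile is
literally one user's exact aggregate value and would otherwise leak
through the audit file (a defect the byte-scan test caught during
development). The test suite enforces the one-way property by scanning
output bytes for any original user id, name, full-precision aggregate or
raw timestamp.

## The synthetic cohort generator

The generator emulates the structure the framework assumes about
wearable data, not wearable physiology. Per metric, user *i* has a latent
mean drawn from Normal(baseline, between-user sd); observations are
Normal(latent, within-user sd); daily counts are Poisson; a fraction of
users are outliers whose latent mean is shifted ±3 between-user sd.
Static attributes are drawn independently per user. Defaults for the
bundled resting-heart-rate preset (10,000 users, one ISO week):

| parameter | default | rationale |
|---|---|---|
| baseline mean | 65 bpm | typical adult resting heart rate |
| between-user sd | 8 bpm | weekly means mostly inside the 50–90 bpm worked-example range, with real tails beyond both caps at n=10,000 |
| within-user sd | 3 bpm | day-to-day variation well below between-user spread |
| measurements/day | Poisson(4), ≥1/week | smartwatch-style sampling; the floor guarantees every user a defined weekly aggregate |
| outlier fraction | 1% | a realistic contamination level; gives the capping step genuine work |
| statics | sex (2), age U(18, 80), country (5), plus a flagged `name` | a plausible quasi-identifier surface that exercises suppression and k-anonymity end to end |

What the generator does **not** emulate: circadian or activity-coupled
structure, longitudinal drift, missingness that correlates with health
status, or cross-metric correlation. Consequently, passing tests show the
*mechanisms* behave as specified on data with the assumed independence
structure; they do not certify re-identification risk for any real
cohort, where temporal patterns and attribute correlations give attackers
more purchase.

## The attack simulator

Each trial targets a random exported user. The attacker's candidate set
starts as all warehouse pseudonyms and is intersected with (a) pseudonyms
whose released bucket value for the known period lies within
`metric_noise_sd` of the value the attacker computes from the target's
raw measurements (exact knowledge is noise 0), and (b) pseudonyms whose
released generalized statics match the target's on every known
attribute. Matching uses only released artifacts — the warehouse table
and, when statics are known, the k-gated static export; the pseudonym
table is used solely to score success and is never visible to the
matcher. Success requires a singleton candidate set containing the
target, so with every bucket holding ≥ k distinct users a metric-only
attacker can never succeed, and the empirical rate respects the 1/k
bound structurally. A combined statics-plus-metric attacker can do
better than 1/k through small intersections of bucket and class — the
known compositional weakness of k-anonymity-style guarantees — and the
risk-curve sweep is the tool for quantifying that residual risk per
configuration. The simulator reports; it deliberately encodes no
judgment about acceptable risk.

## Problem sizes

The bundled preset uses the 10,000-user single-week cohort throughout
(generation ~1 s, full pipeline a few seconds); unit and property tests
run on 200–2,000-user cohorts, which are the smallest sizes at which
30-user bucket thresholds and k=10 class sizes are simultaneously
realistic.
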