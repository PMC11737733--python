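# Methods

This note records the conventions, defaults and design choices behind
`cohortdx`, and what the synthetic-data tests do and do not establish.

## Data model and dates

All dates are whole calendar days; arithmetic is in integer days.
Observation periods that overlap or abut (next start ≤ previous end + 1
day) are merged at load into a canonical non-overlapping set — continuous
observation needs a single interval per stretch — while raw rows are kept
for audit. Persons with multiple disjoint periods are treated as observed
in each period independently. Persons lacking a year of birth are
excluded from age-stratified outputs only, with a logged count; dropping
them everywhere would silently bias the non-age diagnostics.

The five OMOP event domain tables are merged into one clinical-event view
with domain labels and a stable surrogate row id in append order, so any
tie-break downstream is reproducible.

## Cohort instantiation

A definition's entry events produce candidate events per subject
(`first_ever` restricts a concept set to the subject's earliest event in
the whole store, *before* washout — a subject whose first-ever event falls
inside the washout never enters, rather than entering on a later event).
A candidate qualifies when its enclosing normalized observation period
starts at least `prior_observation_days` before it. **The earliest
qualifying candidate is the index**; inclusion rules are evaluated against
that single index date, and a subject whose index fails a rule is out with
no fallback to later candidates. This "limit to earliest event" semantics
is the simplest reading of an entry criterion phrased as "the earliest
of…", and it makes attrition a true sequential filter on subjects.

Rule windows are closed day intervals relative to the index (day 0 = the
index date); an unbounded side is `null` in the JSON schema. Exclusion
criteria are rules with comparator `at_most 0`. Exit is end of continuous
observation or a fixed offset clipped to the observation period.
Disjunctive entry arms too complex for one definition are expressed as
several definitions combined with `union_cohorts` (earliest start wins,
then era-collapse). Instantiation is fully deterministic; no seeds are
involved.

Era-collapse merges a subject's entries whose gap is ≤ `gap_days`. If the
collapse changes counts, a final "era collapse" attrition row is appended
so the last attrition row always equals the emitted cohort's counts.

## Incidence

Person-years use a 365.25-day year and inclusive day counts
(end − start + 1). The denominator population is every person with any
observation time. Each person's at-risk time is left-trimmed by
`washout_days` after each period start and right-censored at their first
cohort entry — the entry day itself is still at risk, so a person entering
on their first observed day contributes exactly one day (≈ 1/365.25
person-years). Repeat entries do not add cases (first-occurrence
incidence); `censor_at_first_entry=False` switches to counting every
entry against uncensored time, since the original tool's convention is
not documented.

Strata: observation time is split at calendar-year boundaries; the age
band within a year is `floor((year − year_of_birth)/10)` (day-precision
birthdates are often absent, so age is year-resolution by design); a case
is assigned by the entry's calendar year and the subject's band and sex at
entry. Rows are emitted for **every subset** of the requested dimensions
(marginals included); strata with zero person-time are omitted. The whole
computation is checked exactly against an independent per-day risk-set
enumeration in the test suite.

## Characterization and balance

Characterization anchors on each subject's **first** entry only, which
prevents a subject re-entering from being double-counted across windows;
whether the original tool uses first or all entries is not documented.
Windows are closed day intervals, day 0 = index, negative = before.
Counts are per-subject deduplicated, so duplicated events never inflate a
prevalence. Demographics (sex, age band at index) are emitted under the
index-date window. With roll-up enabled, each observed concept is also
reported under its hierarchy group: the mapping takes the *nearest
designated group ancestor*, operationalized on a closure table as the
designated ancestor with the fewest descendants (most specific), ties to
the smaller concept id.

Balance uses the binary-prevalence standardized difference
`(p_t − p_c)/√((p_t(1−p_t)+p_c(1−p_c))/2)`, signed, with covariates
absent from one side treated as prevalence 0 there. The statistic is
emitted as null whenever the pooled variance is zero (both proportions at
0 or 1) — including the unequal 0-vs-1 case, where the formula would
yield ±∞. Only binary event-occurrence covariates plus demographics are
emitted; continuous measurement values are out of the default set.

Visit context classifies each (entry, visit) pair into before (visit ends
in [index−30, index−1]), during (starts before index, ends on or after),
simultaneous (starts on index) or after (starts in [index+1, index+30]),
with precedence simultaneous > during > before > after; the four windows
are mutually exclusive except at the simultaneous boundary, which the
precedence resolves. Counts are distinct subjects.

## Results model and censoring

The results model is one CSV per diagnostic family plus a JSON manifest
(row counts and SHA-256 digests) and a metadata record; the schema is
versioned, and no table carries a subject- or person-id column
(schema-enforced). Censoring replaces any count `0 < c < k` with `−k`
(default `k = 5`, configurable) — the negative sentinel distinguishes
"censored" from "zero" and encodes the policy — and nulls derived
quantities (rates, proportions, distribution statistics) instead of
recomputing them, which would allow back-calculating the hidden count.
Zero passes through. The balance table carries only proportions and SMDs,
no raw counts, so the censor leaves it untouched; its inputs were already
subject to censoring on the characterization side of the export.
Censoring is idempotent, and exporting an uncensored bundle is refused.
The run timestamp is excluded from file digests so identical runs are
digest-identical. Proportions and rates are carried at full precision
internally and rounded to 5 significant digits only at serialization.

Merging bundles from several sources concatenates rows keyed by source
name — never cross-source aggregation — and rejects duplicate source
names or mismatched schema versions.

## Synthetic generator

One disease per scenario. Persons get sex (`sex_ratio_female`, default
0.5), an age sampled inside a configured band distribution, and one
observation period of at least a year placed randomly in the calendar
span. True onset follows an exponential waiting time at
`onset_rate_per_1000py` (optionally modulated by sex/age multipliers)
within observed time, so the first-onset process is Poisson and the
empirical rate estimates the configured one without bias. The diagnosis
code appears at onset + coding lag (constant or geometric); with
probability `p_treatment_before_code` a treatment code appears at the
true onset — strictly before the diagnosis whenever the lag is positive —
otherwise treatment follows the diagnosis by `treatment_after_days`.
Codes falling after observation end are lost, which is what makes a
code-based PA's sensitivity ≤ 1 and the truth rate an upper bound.
Symptoms, background noise codes (per person-year) and one visit per
event (category per `visit_model`; inpatient stays 1–7 days) complete the
stream. All draws come from one seeded generator in documented order.

Preset scenarios: `sle_like` (female-skewed onset 5:1, geometric lag mean
45 days, 40% treatment-before-code — the index-misclassification
narrative) and `ad_like` (elderly-skewed onset, shorter treatment delay)
with defaults chosen as plausible order-of-magnitude values for an
autoimmune and a dementia phenotype respectively.

What a green synthetic test establishes: the pipeline's arithmetic
(person-time, windows, set algebra, censoring) and its response to the
injected error mechanisms. What it does not: realistic code frequencies,
correlated care patterns, provider or household structure, multi-disease
interactions, or any real-data performance claim.

## Numerical conventions

- Relative difference between a simple and restrictive PA count:
  `(1 − restrictive/simple)·100`, computed in decimal arithmetic and
  rounded half-up to one decimal.
- Standard deviations in time distributions use the sample convention
  (ddof 1); a single-entry cohort reports sd 0.
- Percentiles use linear interpolation (numpy default).
- Incidence person-years compare to the day-enumeration oracle within
  1e-9 years; cases match exactly.

## Known limitations

- No full Circe grammar: no nested criteria groups, correlated visit
  criteria, or censoring windows; disjunctive arms need `union_cohorts`.
- No source-to-standard vocabulary mapping or vocabulary versioning; no
  missing/orphan-code recommendation.
- Inputs are file directories (CSV/Parquet); no live database
  connections.
- Attrition is sequential only; independent per-rule contribution counts
  are a possible extension.
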