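# Methods

## Unit of analysis and ETL rules

The analysis unit is the patient-day visit.  A visit key concatenates the
patient identifier and the ISO-8601 date (`HN|YYYY-MM-DD`), which is
unambiguous and sorts chronologically within a patient.  Drug codes carry
strength and form in their tail, so the first 4 characters (the *stem*)
identify the compound; all strengths and forms of one compound collapse
onto one stem before any counting.  Transaction building keeps only stems
classifying into the study's ATC classes — antacids (A02A), peptic-ulcer /
GORD drugs (A02B, containing both the H2RA ranitidine and all PPIs), and
NSAIDs (M01A, split into conventional agents and COX-2 inhibitors) — then
deduplicates stems within a visit and drops visits left with fewer than two
distinct stems.  Retained + omitted patient-days always equals the distinct
patient-days in the input, and the result is invariant to input row order.

ICD-10 codes are stored dot-stripped (`K29.7` → `K297`), matching how such
codes are typically exported.  Range membership compares
(letter, two-digit major, right-zero-padded minor) tuples, so `K297` (29.7)
falls inside K20–K29.9 and `K939` (93.9) just outside K90–K93.8; bounds are
inclusive.  For codes with a two-digit major this ordering coincides with
plain string comparison, which the tests exploit as an independent
brute-force check over every code K000–K999.

Age is completed years at the visit date (floor of the exact year
difference).  Dose/frequency codes follow the grammar
`<quantity><CAP|TAB><AM|PM|BID><residue>`; `BID` maps to {morning,
evening}.  Unparseable codes are never fatal — they yield an empty meal
set with the raw string preserved, and a logged warning — because the
audit should continue on partial data.  The `SD` suffix and clinic codes
are opaque strings in the source data and are carried through unmodified.

## Rule mining

Frequent itemsets are found level-wise (Apriori): frequent 1-itemsets,
then candidate k-itemsets joined from frequent (k−1)-itemsets sharing
their first k−2 items, pruned by the anti-monotonicity of support.  All
counting is on exact integers; the minimum support count is the smallest
integer c with c/n ≥ min_support, computed in rational arithmetic so float
thresholds like 0.01 behave exactly.  Rules are every ordered partition of
a frequent itemset into non-empty antecedent and consequent, filtered by
confidence.  Defaults mirror drug-pair screening practice: support ≥ 1%,
confidence ≥ 50%, and rules capped at two items (both directions of a pair
are distinct rules); larger itemsets are mined and exposed via
`max_rule_items`.

Display rounding is half-away-from-zero at 4 decimals, implemented on
integer ratios (`round_ratio`) rather than binary floats — several
reference values (e.g. a confidence of 669/687 = 0.97380…) round correctly
only under count-exact arithmetic.  Output order (descending lift, then
descending support, then antecedent) is a deterministic tie-break, not a
statistical statement.  No multiple-testing adjustment is applied to rule
statistics.

A brute-force oracle (`brute_force_rules`) enumerates the full subset
lattice and all rule partitions on inputs with ≤ 12 distinct items.  It is
an independent code path used only in tests, where property-based
generation asserts exact agreement with the Apriori path (same rules, same
integer counts).

## Guideline audit

H2RA + PPI visits are concordant iff a K21-prefix (GORD) diagnosis is
recorded at the visit.  COX-2 + PPI visits are discordant iff *none* of
age ≥ 60, GI-complication diagnosis (the three K-ranges above), or aspirin
exposure holds; this makes discordance monotone — adding a risk criterion
can never turn a concordant visit discordant.  Aspirin exposure means an
aspirin stem (ASPT, ASA., CAPN) prescribed at the same visit or within a
configurable look-back/forward window in days (default 0, i.e. same day),
or an explicit co-therapy flag on the visit context.  Same-meal and
same-clinic flags compare parsed dose schedules and clinic codes across
the two drug classes of the pattern.

Summary tables partition findings into age bands (≥ 60, 50–59, < 50 —
three bands that cover all ages), GI complication yes/no, aspirin yes/no
and the joint discordance category; the H2RA pattern is summarised as GORD
vs non-GORD plus a per-diagnosis frequency table in which each visit is
labelled by its GORD code if present, else its first GI-range code, else
"no GI diagnosis".  Percentages are 100·count/total rounded
half-away-from-zero to 1 decimal; each partition's counts sum to the
total exactly, so percentages sum to 100 ± 0.2 rounding slack.  Visits
without demographic context are reported separately and excluded from
percentage denominators, since no missing-data rule exists for them.

## Synthetic cohorts

The generator emulates the data sources the pipeline expects, not any real
hospital.  Defaults follow the outpatient population the tool targets:
mean age 48.4 (SD 21.4) years truncated at 0, 34% male, 4.7 (SD 4.4)
visits per person-year (negative binomial, since utilisation is
overdispersed; Poisson when the requested SD is not), two fiscal years of
visit dates, background GI-complication coding at 1.8% of visits and
arthritis coding at 0.74%.  Per-visit drug inclusion is Bernoulli per stem
at configurable prevalences; a boosted pair (x, y, b) is sampled
sequentially — x from its marginal, then y conditioned so the joint
probability is exactly b·P(x)·P(y) while preserving P(y) — which makes the
configured boost the analytic expectation of the mined lift.  Boosted
pairs must be disjoint; overlapping pairs raise a parameter error rather
than silently distorting marginals.  GI/GORD diagnosis codes attach with
elevated probability (default 0.30) at visits carrying a PPI, creating the
diagnosis–prescription correlation the audit relies on.  All randomness
flows through one integer seed; identical parameters give byte-identical
CSVs.

What the generator does **not** model: visit-level temporal
autocorrelation, refill behaviour, physician-level prescribing habits, or
any joint age × drug × diagnosis structure beyond the mechanisms above.
Passing tests on synthetic cohorts therefore validate the pipeline's
correctness and calibration, not any clinical claim about real data.

## Reconstruction fixtures and the inversion oracle

Published summary tables print rounded statistics over a known transaction
count n.  `invert_printed_rule` exhaustively searches integer joint and
marginal counts whose exact ratios round (half-away-from-zero, 4 dp) to
the printed support/confidence; it returns *all* solutions, and when none
exists it raises an error carrying the nearest miss — rounded tables are
not always internally consistent, and the oracle documents this rather
than hiding it (e.g. a printed support of 0.0552 at n = 6168 has no
integer solution; the nearest count, 340, rounds to 0.0551).

`make_pair_fixture` realises recovered counts as a transaction set of
two-item visits, padding with inert filler items whose totals stay
strictly below the mining support threshold so no filler rule can survive
(for toy fixtures where n·min_support ≤ 1, fillers are single-use, the
closest feasible design).  `make_table2_fixture` is a fixed block design
over 6,168 transactions — 2,600 × {OMPZ, XAND}; per antecedent stem 70 ×
{stem, OMPZ} + 50 × {stem, filler}; 2,000 × {XAND, filler}; 368 filler
pairs, every filler below 62 occurrences — yielding exactly 12
single-item rules at the default thresholds.  Audit fixtures materialise
requested joint category counts (age band × GI diagnosis × aspirin, or a
per-diagnosis breakdown) as deterministic visits with contexts.

## Numerical and testing choices

Problem sizes were chosen to keep the default suite fast while leaving the
statistical checks well-powered: property-based mining equivalence runs on
≤ 25 transactions over ≤ 6 items (exhaustive oracle territory), calibration
checks use 50,000 simulated visits with Monte-Carlo standard errors
estimated from 10 independent batches, and the single-drug exclusion filter
is exercised on a full-size 134,285-patient-day synthetic input.  Test
tolerances on stochastic quantities are 3 Monte-Carlo SEs; everything
deterministic is asserted exactly, at printed precision.

Known limitations: the catalog ships one inferred entry (stem MOBC,
presumed a meloxicam brand absent from the published drug list) so
demonstration fixtures can include it; the per-diagnosis summary labels a
visit by a single diagnosis even if several GI codes co-occur; and the
pipeline assumes one row per prescribed drug per visit — quantities and
refills are out of scope.
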