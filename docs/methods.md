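# Methods

## Problem and model

National immunization programs usually estimate vaccination coverage
administratively: doses administered divided by a target population. The
denominator is live births (LB) for birth-dose vaccines such as BCG and
surviving infants (SI) for vaccines completed in the first year of life such
as the third dose of DTP-containing vaccine (DTP3). Errors in these
denominators translate directly into coverage errors, and the distortion
grows with coverage: if the true target population is misstated by a
relative error *e*, measured coverage is `c / (1 + e)`, so a 10% undercount
turns a true 90% coverage into 100% (+10 percentage points) but a true 10%
into only 11.1% (+1.1 points). `coverage_error_from_denominator_error`
implements this closed form.

`denomqa` assesses the quality of a reported denominator panel — one
country × year × vaccine reporting event per cell — with four derived
statistics and nine binary flags per country-year:

* administrative coverage, `100 · doses / target`;
* year-to-year percent difference, `100 · (v₂/v₁ − 1)`, applied to the LB
  series, the SI series, and both coverage series;
* percent difference from a reference demographic projection,
  `100 · (reported − reference) / reference`, signed: negative means the
  country reported fewer than the reference projects;
* implied infant mortality rate, `1000 · (LB − SI) / LB`, computed from the
  country's own same-year reports.

Flags: (F1, F2) reported LB/SI missing; (F3) |year-to-year difference| of
LB or SI above 10%; (F4) likewise for BCG or DTP3 coverage; (F5) coverage
above 100%; (F6) negative implied IMR (more surviving infants than live
births is infeasible); (F7, F8) |difference from the reference LB/SI| above
10%; (F9) DTP3 target differing from the DTP1 target, which should be the
same cohort. F3 and F4 are each a single flag that fires when either of
their component series exceeds the threshold; the flag-count summation per
country-year therefore ranges 0–9. The summary tables keep the component
series separate and additionally tally them at an auxiliary 5% threshold.

## Eligibility cascade

Reporting events enter the analysis set through a fixed-precedence cascade,
evaluated per event: (1) years before a country's first reporting year,
(2) countries without reference estimates, (3) vaccine-specific criteria —
for BCG: vaccine not in the national schedule, target not the full
birth cohort, or target age over one year; for DTP3: target age over one
year; with optional per-year overrides for schedules that changed mid-panel
— and (4) countries that never reported the vaccine's target. Each cell
gets exactly one decision with its first matching reason, so tallies always
reconcile with the grid. On the study-scale metadata (194 countries ×
2000–2016 = 3,298 cells per vaccine) the cascade leaves 2,565 BCG events
across 153 countries and 2,939 DTP3 events across 174 countries.

The per-event (rather than per-country) evaluation of schedule criteria is
deliberate: a country can be BCG-ineligible for part of the panel only, so
the excluded-event count need not be a multiple of 17. Metadata therefore
carries optional `bcg_excluded_years`/`dtp3_excluded_years` columns.

## Statistic evaluability

Every statistic is missing exactly when a required input is missing or
ineligible. Year-to-year differences require two *consecutive* eligible,
non-missing years and never bridge a gap: removing year *t* makes both the
(t−1, t) and (t, t+1) pairs non-evaluable. A flag whose inputs are absent is
recorded `evaluable = False, fired = False`, never silently unfired, so
every summary base can be audited. Percentages in rendered tables are
rounded half away from zero; all comparisons use unrounded values.

## Numerical choices

* All thresholds are strict (`> 10%`, `> 100%`, `< 0`): boundary values do
  not fire. Because ratios like 1100/1000 carry ~1e−16 relative float
  error, threshold comparisons treat values within 1e−9 relative of the
  threshold as equal to it; an exactly-10% jump therefore never fires on
  round-off.
* A reported target of 0 is rejected at ingest (division safety; a zero
  cohort is not a non-report), and missing is never coerced to 0.
* F9 compares integer targets for exact inequality; with a missing DTP1
  target it is non-evaluable, since a mismatch cannot be asserted against
  an absent value.
* Statistics are carried at full double precision; integer rounding happens
  only in report rendering.

## Synthetic data generator

The generator emulates the statistical structure of a national reporting
panel without any real data. Clean baseline per country: a log-uniform
baseline LB between 20 thousand and 5 million, per-year growth drawn
uniformly from 0.2–3%, an infant mortality rate of 2–80 per 1000 (so
reference SI = LB · (1 − IMR/1000) ≤ LB always), reported values equal to
rounded reference values, DTP1 target equal to the DTP3 target, and doses
set from country-level true coverage drawn from 60–99%. A clean panel fires
zero flags: growth stays below the 5% auxiliary threshold, coverage is flat
and under 100%, and reported equals reference.

Anomalies are planted per country-year with configurable Bernoulli rates
(defaults of 4–10% per kind per cell, in the neighbourhood of how often
such inconsistencies appear in real reporting), drawn in a documented order
(countries → years → kinds) from one seeded generator. Magnitudes are
bounded away from the thresholds by at least 2 percentage points (jumps and
reference divergences of 15–50/60%, planted coverage of 115–145%, SI set to
1.02–1.15 × LB), so recovery is unambiguous. Planting is surgical — doses
and the DTP1 target are co-scaled so a planting fires only its own flag —
and unavoidable knock-ons are declared per kind (a denominator jump at *t*
necessarily fires the reference comparison at *t* and the fluctuation flag
again at *t+1*; planted >100% coverage fires the coverage-fluctuation flag
at *t* and *t+1*). The recovery scorer counts such firings as *induced*,
not false. At most one anomaly is planted per country within any three
consecutive years so plantings never interact; skipped attempts do not
enter the truth ledger, which therefore remains exhaustive, and realized
anomaly counts sit somewhat below the nominal rates on dirty
configurations. With default magnitudes, precision and recall against the
truth ledger are exactly 1.0 for every anomaly kind.

What the generator does **not** emulate: demographic realism beyond smooth
growth (no age structure, migration shocks, or census-revision mechanics),
spatial or temporal correlation of anomalies, numerator-side errors other
than the planted >100% coverage, and the country-specific idiosyncrasies of
real reporting systems. Passing recovery tests therefore demonstrates that
the flag rules detect exactly what they define, under conditions where
detection is possible — not that flagged real-world events are truly
erroneous, which always requires follow-up investigation.

## Study-scale builders

`make_study_metadata` reproduces the eligibility universe of a 194-member,
2000–2016 reporting system: 3 late joiners first reporting in 2006, 2011
and 2002 (19 events); 10 small states without reference projections (170
events); 31 countries excluded from the BCG analysis (527 events, split
across not-in-schedule, not-full-cohort, target-over-age-one and
never-reported reasons), 10 of which are also excluded from DTP3 (170
events); and 17 per-year schedule-override exclusions split 9 + 8 across
two otherwise-included countries, bringing BCG-specific exclusions to 544
events while keeping the included-country count at 153. The identities are
synthetic; only the tallies are meaningful. Exact-count planting helpers
(`plant_missing_targets`, `plant_reference_divergence`) impose a chosen
number of missing events or signed reference divergences on the clean
study-scale panel, which is how the acceptance script reconstructs
missingness percentages (194/2,565 → 8%, 274/2,939 → 9%) and
direction-of-difference tallies (372 higher + 508 lower = 880 for LB; 390 +
509 = 899 for SI) from a live pipeline run.

## Aggregation conventions

* Indicator tables: the country base per indicator is the set of countries
  with at least one *evaluable* event for that indicator, which is why
  bases vary between indicators; country tallies are nested (fired in ≥10
  years ⊆ ≥5 years ⊆ any year).
* Flag-count distribution: per selected year, countries are binned by
  number of fired flags (0, 1, 2, 3, 4, 5+); bins sum to the countries with
  at least one evaluable flag that year.
* Regional series: a country-year contributes to a vaccine's regional sums
  iff its event is in the analysis set; a missing report contributes 0 on
  the reported side while its reference value still counts, so
  non-reporting by a large country appears as a dip in the reported series
  against a stable reference — the signature the regional comparison is
  designed to surface.

## Problem sizes

The analysis drivers and tests run the full 194 × 17 panel (the generator
produces it in well under a second); recovery checks use a 50-country × 17-year
panel, and oracle-parity checks use 100 random panels of at most 5 × 5,
where a brute-force re-evaluation of each rule is feasible and independent.

## Known limitations

* Implied IMR uses same-year LB and SI; genuine cross-cohort carryover
  (children born late in year *t−1* vaccinated in year *t*) can push real
  SI above LB without error, and is not modelled.
* Numerator (doses) quality is assessed only through the coverage cap.
* The flag thresholds (10%, 5%, 100%, 0) are conventions, not optimized
  decision boundaries; the `Thresholds` config exposes them.
* Reference projections are treated as the comparator, not as truth;
  a large reported-vs-reference divergence identifies a discrepancy, not
  which side is wrong.
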