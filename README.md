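# denomqa

Quality and consistency assessment of the target-population denominators
behind administrative immunization coverage.

Most countries estimate vaccination coverage administratively — doses
administered divided by a target population: live births (LB) for
birth-dose vaccines such as BCG, surviving infants (SI) for first-year
vaccines such as DTP3. When the denominator is wrong, coverage is wrong,
and increasingly so as coverage rises: a denominator misstated by relative
error *e* turns true coverage *c* into *c/(1+e)*, so a 10% undercount
inflates 90% coverage by a full 10 percentage points. `denomqa` is for
epidemiologists and immunization-program analysts who need to screen a
reported country × year × vaccine panel for denominator problems before
trusting the coverage numbers built on it.

The package implements:

* **an eligibility cascade** over the full country × year reporting grid
  (pre-reporting years, no reference estimates, vaccine-specific schedule
  criteria, never-reported targets), producing an auditable per-event
  exclusion ledger;
* **four derived statistics** per country-year: administrative coverage
  `100·doses/target`; year-to-year percent difference `100·(v₂/v₁−1)` of
  denominators and of coverage; signed percent difference from reference
  demographic projections `100·(reported−ref)/ref`; and the implied infant
  mortality rate `1000·(LB−SI)/LB`;
* **nine accuracy/consistency flags** per country-year: LB missing, SI
  missing, denominator fluctuation >10%, coverage fluctuation >10%,
  coverage >100%, negative implied IMR, LB and SI diverging >10% from the
  reference, and a DTP1/DTP3 target mismatch — all thresholds strict,
  non-evaluable cases tracked explicitly;
* **summary surfaces**: per-indicator event and country tallies (any year /
  ≥5 years / ≥10 years, at 5% and 10% threshold variants), per-year
  distributions of countries by flag count, direction-of-difference splits,
  and regional sums of reported vs reference denominators;
* **a seeded synthetic-panel generator** with planted anomalies and a truth
  ledger, so the whole pipeline is testable with no external data, plus a
  precision/recall scorer for anomaly recovery.

## Worked example

The numbered drivers under `analysis/` run the pipeline on a synthetic
194-country, 2000–2016 panel and write tables under `results/`:

```sh
python analysis/01_simulate.py    # panel + truth ledger
python analysis/02_flags.py      # eligibility ledger + statistics + flags
python analysis/03_summarize.py  # indicator tables, distributions, figures
python analysis/04_recovery.py   # precision/recall vs the truth ledger
```

`01_simulate.py` plants anomalies at a few percent per country-year and
reports what it planted:

```
Simulated 194 countries x 17 years (9894 reporting events) with seed 20160101.
Planted 840 anomalies over 3298 country-years (25.5% of cells):
  ref_divergence_gt10    213
  denom_jump_gt10        131
  dtp_mismatch           110
  coverage_gt100         110
  missing_lb             102
  missing_si             99
  negative_imr           75
```

`02_flags.py` prints the firings per flag — for example
`F6_NEG_IMR 75 / 3097` means the negative-implied-IMR rule was evaluable
for 3,097 country-years (both LB and SI reported) and fired for exactly the
75 planted inversions. `03_summarize.py` tabulates indicators and bins
countries by how many flags they fired in 2001/2006/2011/2016, and
`04_recovery.py` closes the loop against the truth ledger:

```
       anomaly_kind  n_planted  n_recovered  recall  n_false_positive  precision
         missing_lb        102          102     1.0                 0        1.0
         missing_si         99           99     1.0                 0        1.0
    denom_jump_gt10        131          131     1.0                 0        1.0
     coverage_gt100        110          110     1.0                 0        1.0
       negative_imr         75           75     1.0                 0        1.0
ref_divergence_gt10        213          213     1.0                 0        1.0
       dtp_mismatch        110          110     1.0                 0        1.0
```

Recall 1.0 means every planted anomaly fired its flag at the planted
country-year; precision 1.0 means every firing is either a planting or a
declared knock-on of one (e.g. a one-year denominator spike legitimately
fires the fluctuation flag again when the series reverts).

The same pipeline is scriptable on your own CSVs through the CLI:

```sh
denomqa simulate --out panel/ --seed 7
denomqa flags --reported panel/reported.csv --reference panel/reference.csv \
              --meta panel/country_meta.csv --out run/
denomqa summarize --flags run/flags.csv --indicators run/indicators.csv --out summary/
denomqa recover --flags run/flags.csv --truth panel/truth_ledger.csv --out rec/
```

Input schemas are documented in `denomqa.ingest`; every run writes a JSON
manifest with input checksums, configuration and seed.

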