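"""Aggregate flags into the summary surfaces and figures.

Writes the indicator summary table (events and country tallies per
indicator and threshold variant), the flag-count distribution for 2001,
2006, 2011 and 2016, the direction-of-difference split for the reference
comparisons, and regional sums of reported vs reference denominators, under
results/summary/ (figures under results/summary/figures/).
"""

from pathlib import Path

import pandas as pd

from denomqa import (
    direction_analysis,
    flag_count_distribution,
    regional_aggregate,
    sum_flags_per_country_year,
    tabulate_indicator_summary,
)
from denomqa.eligibility import read_decisions
from denomqa.flags import read_flags
from denomqa.ingest import read_country_meta, read_reference_panel, read_reported_panel
from denomqa import plotting

ROOT = Path(__file__).resolve().parent.parent / "results"
YEARS = [2001, 2006, 2011, 2016]


def main() -> None:
    flags = read_flags(ROOT / "flags" / "flags.csv")
    indicators = pd.read_csv(ROOT / "flags" / "indicators.csv")
    decisions = read_decisions(ROOT / "flags" / "decisions.csv")
    meta = read_country_meta(ROOT / "panel" / "country_meta.csv")
    reports = read_reported_panel(ROOT / "panel" / "reported.csv")
    reference = read_reference_panel(ROOT / "panel" / "reference.csv")

    out = ROOT / "summary"
    figures = out / "figures"
    figures.mkdir(parents=True, exist_ok=True)

    table = tabulate_indicator_summary(indicators)
    table.to_csv(out / "indicator_summary.csv", index=False)

    per_cy = sum_flags_per_country_year(flags)
    per_cy.to_csv(out / "flag_counts_per_country_year.csv", index=False)
    dist = flag_count_distribution(per_cy, YEARS)
    dist.to_csv(out / "flag_count_distribution.csv", index=False)

    direction = direction_analysis(flags)
    direction.to_csv(out / "direction_analysis.csv", index=False)

    regional = regional_aggregate(reports, reference, decisions, meta)
    regional.to_csv(out / "regional_series.csv", index=False)

    plotting.plot_flag_count_distribution(dist, figures / "flag_count_distribution.png")
    plotting.plot_regional_series(regional, figures / "regional_series.png")
    plotting.plot_coverage_error_curve(figures / "coverage_error_vs_coverage.png")

    print("Indicator summary (flagging-threshold variants):")
    main_rows = table[~table["threshold_variant"].eq(5.0)]  # drop aux-threshold variants
    for row in main_rows.itertuples():
        print(f"  {row.indicator:<14s} {row.events_fired:>4d}/{row.events_evaluable:<5d}"
              f" events ({row.events_fired_pct}%), "
              f"{row.countries_fired_any_year}/{row.countries_total} countries any year")
    print("\nCountries by number of flags fired:")
    wide = dist.pivot(index="year", columns="bin", values="n_countries")
    print(wide.to_string())
    for row in direction.itertuples():
        print(f"\n{row.flag_id}: {row.events_fired} fired = "
              f"{row.higher_than_reference} above + {row.lower_than_reference} below reference")
    print(f"\nWrote summary tables to {out} and figures to {figures}")


if __name__ == "__main__":
    main()
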