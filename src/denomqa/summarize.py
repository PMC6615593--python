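"""Aggregate flags into summary tables: indicator tallies, flag-count
distributions over time, direction-of-difference counts, and regional sums of
reported vs reference denominators.

Printed percentages are rounded to the nearest integer, half away from zero;
all tallies are computed from unrounded statistics.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from denomqa.flags import FLAG_IDS

DISTRIBUTION_BINS = ("0", "1", "2", "3", "4", "5+")


def round_half_away(x: float) -> int:
    """Round to nearest integer with ties away from zero (so 7.5 -> 8, -7.5 -> -8)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def sum_flags_per_country_year(flags: pd.DataFrame) -> pd.DataFrame:
    """Count fired flags per country-year (0..9).

    Non-evaluable flags contribute zero.  Country-years with at least one
    evaluable flag appear in the result (with 0 when nothing fired); fully
    non-evaluable country-years do not.
    """
    evaluable = flags[flags["evaluable"]]
    counts = (
        evaluable.groupby(["country_code", "year"], sort=True)["fired"]
        .sum()
        .astype(int)
        .rename("n_flags")
        .reset_index()
    )
    return counts


def tabulate_indicator_summary(indicators: pd.DataFrame) -> pd.DataFrame:
    """Summary-table tallies per indicator and threshold variant.

    For each (indicator, threshold_variant): the number of evaluable
    reporting events, the number and integer percent fired, and country
    tallies — countries with at least one evaluable event (the base), and
    countries flagged in any year, in 5 or more years, and in 10 or more
    years, each with integer percents of the base.
    """
    rows = []
    group_cols = ["indicator", "threshold_variant"]
    for (indicator, variant), grp in indicators.groupby(group_cols, dropna=False, sort=False):
        ev = grp[grp["evaluable"]]
        events_evaluable = len(ev)
        events_fired = int(ev["fired"].sum())
        per_country_fired = ev.groupby("country_code")["fired"].sum()
        countries_total = int(ev["country_code"].nunique())
        any_year = int((per_country_fired >= 1).sum())
        ge5 = int((per_country_fired >= 5).sum())
        ge10 = int((per_country_fired >= 10).sum())

        def pct(k, n):
            return round_half_away(100.0 * k / n) if n else 0

        rows.append({
            "indicator": indicator,
            "threshold_variant": variant,
            "events_evaluable": events_evaluable,
            "events_fired": events_fired,
            "events_fired_pct": pct(events_fired, events_evaluable),
            "countries_total": countries_total,
            "countries_fired_any_year": any_year,
            "countries_fired_any_year_pct": pct(any_year, countries_total),
            "countries_fired_ge5_years": ge5,
            "countries_fired_ge5_years_pct": pct(ge5, countries_total),
            "countries_fired_ge10_years": ge10,
            "countries_fired_ge10_years_pct": pct(ge10, countries_total),
        })
    return pd.DataFrame(rows)


def flag_count_distribution(per_country_year: pd.DataFrame, years) -> pd.DataFrame:
    """Histogram of countries by number of fired flags, for selected years.

    Bins are 0, 1, 2, 3, 4 and "5+"; for each requested year the bin counts
    sum to the number of countries with at least one evaluable flag that
    year.  Requesting a year absent from the panel's range raises.
    """
    years = list(years)
    available = set(per_country_year["year"].unique())
    if available:
        lo, hi = min(available), max(available)
        for y in years:
            if y < lo or y > hi:
                raise ValueError(f"year {y} outside panel range {lo}-{hi}")
    rows = []
    for y in years:
        sub = per_country_year[per_country_year["year"] == y]
        binned = np.minimum(sub["n_flags"].to_numpy(int), 5) if len(sub) else np.array([], int)
        for i, label in enumerate(DISTRIBUTION_BINS):
            rows.append({"year": y, "bin": label, "n_countries": int((binned == i).sum())})
    return pd.DataFrame(rows)


def direction_analysis(flags: pd.DataFrame) -> pd.DataFrame:
    """Split fired reference-divergence flags by sign of the difference.

    For each of the two reference-comparison flags, counts fired events where
    the reported denominator exceeded the reference by more than the
    threshold ("higher") versus fell short by more than the threshold
    ("lower"); higher + lower equals the fired total.
    """
    rows = []
    for flag_id in ("F7_LB_REF_DIFF_GT10", "F8_SI_REF_DIFF_GT10"):
        sub = flags[(flags["flag_id"] == flag_id) & flags["fired"]]
        higher = int((sub["statistic_value"] > sub["threshold"]).sum())
        lower = int((sub["statistic_value"] < -sub["threshold"]).sum())
        rows.append({
            "flag_id": flag_id,
            "events_fired": len(sub),
            "higher_than_reference": higher,
            "lower_than_reference": lower,
        })
    return pd.DataFrame(rows)


def regional_aggregate(
    reports: pd.DataFrame,
    reference: pd.DataFrame,
    decisions: pd.DataFrame,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Regional sums of reported vs reference denominators per year.

    A country-year contributes to a vaccine's sums iff its reporting event is
    included in the analysis set; within that set a missing reported value
    contributes 0 to the reported sum while its reference value still counts,
    so non-reporting by a large country shows up as a dip in the reported
    series against a stable reference series.
    """
    known = set(meta["country_code"])
    unknown = set(decisions["country_code"]) - known
    if unknown:
        raise ValueError(f"decisions reference countries without metadata: {sorted(unknown)[:5]}")

    region_of = meta.set_index("country_code")["region"]
    ref = reference.set_index(["country_code", "year"])

    frames = {}
    for vaccine, ref_col, label in (
        ("BCG", "live_births", "lb"),
        ("DTP3", "surviving_infants", "si"),
    ):
        dec = decisions[(decisions["vaccine"] == vaccine) & decisions["included"]]
        idx = pd.MultiIndex.from_frame(dec[["country_code", "year"]])
        rep = (
            reports.loc[reports["vaccine"] == vaccine]
            .set_index(["country_code", "year"])["target_population"]
            .reindex(idx)
            .to_numpy(dtype=float, na_value=np.nan)
        )
        sub = dec[["country_code", "year"]].copy()
        sub["region"] = region_of.reindex(sub["country_code"]).to_numpy()
        sub[f"reported_{label}"] = np.nan_to_num(rep)
        sub[f"reference_{label}"] = ref[ref_col].reindex(idx).to_numpy(dtype=float)
        frames[label] = (
            sub.groupby(["region", "year"], sort=True)[[f"reported_{label}", f"reference_{label}"]]
            .sum()
        )

    out = frames["lb"].join(frames["si"], how="outer").fillna(0.0).reset_index()
    return out[["region", "year", "reported_lb", "reported_si", "reference_lb", "reference_si"]]


def flag_wide_table(flags: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long flag ledger to one row per country-year, one column per flag."""
    fired = flags.pivot_table(
        index=["country_code", "year"], columns="flag_id", values="fired", aggfunc="any"
    ).reindex(columns=list(FLAG_IDS))
    return fired.fillna(False).astype(bool).reset_index()
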