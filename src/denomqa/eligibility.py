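"""Inclusion/exclusion cascade over the country x year reporting grid.

Every member state has one reporting opportunity per vaccine per year; the
full grid is therefore |countries| x |years| cells per vaccine.  Cells are
excluded, in a fixed precedence order, when

1. the year precedes the country's first reporting year (late joiners),
2. the country has no reference demographic estimates,
3. vaccine-specific criteria fail — for BCG: the vaccine is not in the
   national schedule, the reported target is not the full live-birth cohort,
   or the target age is over one year; for DTP3: the target age is over one
   year; either vaccine may additionally carry per-year schedule overrides,
4. the country never reported a target population for the vaccine.

Each cell receives exactly one decision with its first matching exclusion
reason, giving an auditable ledger whose counts reconcile with the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from denomqa.ingest import parse_year_overrides

EXCLUSION_REASONS = (
    "NONE",
    "PRE_MEMBERSHIP_OR_PRE_REPORTING",
    "NO_REFERENCE_ESTIMATES",
    "VACCINE_NOT_IN_SCHEDULE",
    "TARGET_NOT_FULL_COHORT",
    "TARGET_AGE_OVER_ONE",
    "NEVER_REPORTED_TARGET",
)

DECISION_COLUMNS = ["country_code", "year", "vaccine", "included", "exclusion_reason"]


@dataclass(frozen=True)
class EligibilitySummary:
    """Reconciled tallies for one vaccine's cascade."""

    vaccine: str
    grid_total: int
    excluded_by_reason: dict[str, int]
    included_events: int
    included_countries: int

    def __post_init__(self) -> None:
        total = self.included_events + sum(self.excluded_by_reason.values())
        if total != self.grid_total:
            raise ValueError(
                f"eligibility tallies do not reconcile: {self.included_events} included "
                f"+ {sum(self.excluded_by_reason.values())} excluded != grid {self.grid_total}"
            )


def build_event_grid(meta: pd.DataFrame, year_range: tuple[int, int]) -> pd.DataFrame:
    """Cross every country in ``meta`` with every year in the inclusive range.

    Returns a DataFrame of (country_code, year) cells ordered by country then
    year; with 194 countries and 2000-2016 this is the 3,298-cell grid of
    possible reporting events per vaccine.
    """
    lo, hi = year_range
    if hi < lo:
        raise ValueError(f"empty year range {year_range}")
    if len(meta) == 0:
        raise ValueError("empty country metadata")
    countries = sorted(meta["country_code"].unique())
    years = range(lo, hi + 1)
    return pd.DataFrame(
        [(c, y) for c in countries for y in years], columns=["country_code", "year"]
    )


def _vaccine_specific_reason(row: pd.Series, vaccine: str, year: int) -> str | None:
    """First failing vaccine-specific criterion for this country-year, if any."""
    if vaccine == "BCG":
        if not row["bcg_in_schedule"]:
            return "VACCINE_NOT_IN_SCHEDULE"
        if not row["bcg_target_is_full_birth_cohort"]:
            return "TARGET_NOT_FULL_COHORT"
        if not row["bcg_target_age_under_one"]:
            return "TARGET_AGE_OVER_ONE"
        if year in parse_year_overrides(row.get("bcg_excluded_years", "")):
            return "VACCINE_NOT_IN_SCHEDULE"
    elif vaccine == "DTP3":
        if not row["dtp3_target_age_under_one"]:
            return "TARGET_AGE_OVER_ONE"
        if year in parse_year_overrides(row.get("dtp3_excluded_years", "")):
            return "VACCINE_NOT_IN_SCHEDULE"
    else:
        raise ValueError(f"eligibility is assessed for BCG and DTP3, not {vaccine!r}")
    return None


def apply_eligibility(
    grid: pd.DataFrame, meta: pd.DataFrame, vaccine: str
) -> tuple[pd.DataFrame, EligibilitySummary]:
    """Apply the exclusion cascade for one vaccine over the event grid.

    Returns the per-cell decision ledger (one row per grid cell with
    ``included`` and ``exclusion_reason``) and a reconciled summary.
    """
    missing = set(grid["country_code"]) - set(meta["country_code"])
    if missing:
        raise ValueError(f"no metadata for grid countries: {sorted(missing)[:5]}")

    meta_by_country = {row["country_code"]: row for _, row in meta.iterrows()}
    ever_col = "ever_reported_bcg_target" if vaccine == "BCG" else "ever_reported_dtp3_target"

    reasons = []
    for country, year in grid.itertuples(index=False):
        row = meta_by_country[country]
        if year < row["first_reporting_year"]:
            reasons.append("PRE_MEMBERSHIP_OR_PRE_REPORTING")
        elif not row["has_reference_estimates"]:
            reasons.append("NO_REFERENCE_ESTIMATES")
        elif (vax_reason := _vaccine_specific_reason(row, vaccine, year)) is not None:
            reasons.append(vax_reason)
        elif not row[ever_col]:
            reasons.append("NEVER_REPORTED_TARGET")
        else:
            reasons.append("NONE")

    decisions = grid.copy()
    decisions["vaccine"] = vaccine
    decisions["exclusion_reason"] = reasons
    decisions["included"] = decisions["exclusion_reason"] == "NONE"
    decisions = decisions[DECISION_COLUMNS]

    excluded = decisions[~decisions["included"]]
    summary = EligibilitySummary(
        vaccine=vaccine,
        grid_total=len(decisions),
        excluded_by_reason=excluded["exclusion_reason"].value_counts().to_dict(),
        included_events=int(decisions["included"].sum()),
        included_countries=included_country_count(decisions),
    )
    return decisions, summary


def included_country_count(decisions: pd.DataFrame) -> int:
    """Number of countries with at least one included reporting event."""
    if len(decisions) == 0:
        raise ValueError("empty decision ledger")
    return int(decisions.loc[decisions["included"], "country_code"].nunique())


def write_decisions(decisions: pd.DataFrame, path) -> None:
    decisions.to_csv(path, index=False)


def read_decisions(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"country_code": str, "vaccine": str})
    df["year"] = df["year"].astype(int)
    df["included"] = df["included"].astype(bool)
    return df[DECISION_COLUMNS]
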