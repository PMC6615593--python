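"""Read and validate the three CSV inputs into canonical pandas panels.

Three tables drive the pipeline:

* the **reported panel** — one row per (country, year, vaccine) reporting
  event, carrying doses administered and the reported target population;
* the **reference panel** — one row per (country, year) with projected live
  births and surviving infants from the demographic reference source;
* the **country metadata** — region, membership/reporting start years and
  schedule-eligibility booleans used by the inclusion cascade.

Conventions: comma-separated UTF-8 with a header; missing values are empty
cells or the literal ``NA``; countries are identified by ISO3 code only.
Missing is never coerced to zero — an empty target cell round-trips as a
missing value, and a reported target of 0 is rejected at ingest (a country
that reports nothing is distinguishable from one that reports a zero cohort).
"""

from __future__ import annotations

import pandas as pd

VACCINES = ("BCG", "DTP1", "DTP3")
REGIONS = ("AFR", "AMR", "EMR", "EUR", "SEAR", "WPR")

REPORTED_COLUMNS = [
    "country_code",
    "year",
    "vaccine",
    "doses_administered",
    "target_population",
]
REFERENCE_COLUMNS = ["country_code", "year", "live_births", "surviving_infants"]
META_COLUMNS = [
    "country_code",
    "region",
    "membership_start_year",
    "first_reporting_year",
    "has_reference_estimates",
    "bcg_in_schedule",
    "bcg_target_is_full_birth_cohort",
    "bcg_target_age_under_one",
    "dtp3_target_age_under_one",
    "ever_reported_bcg_target",
    "ever_reported_dtp3_target",
]
# Optional per-year schedule overrides: ';'-separated years during which the
# vaccine-specific inclusion criteria fail even though the country-level
# booleans hold (schedules change over time).
META_OPTIONAL_COLUMNS = ["bcg_excluded_years", "dtp3_excluded_years"]

_NA_VALUES = ["", "NA"]
_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False,
}


class PanelValidationError(ValueError):
    """A parsed input violates a schema or domain invariant."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelValidationError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


def _parse_bool(series: pd.Series, column: str, path) -> pd.Series:
    out = series.astype(str).str.strip().str.lower().map(_BOOL_MAP)
    if out.isna().any():
        bad = series[out.isna()].iloc[0]
        raise PanelValidationError(f"{path}: column {column!r}: unparseable boolean {bad!r}")
    return out.astype(bool)


def read_reported_panel(path, year_range: tuple[int, int] = (2000, 2016)) -> pd.DataFrame:
    """Read a reported-data panel of (country, year, vaccine) events.

    Parameters
    ----------
    path : str or pathlib.Path
        CSV file with columns ``country_code,year,vaccine,doses_administered,
        target_population``.
    year_range : (int, int)
        Inclusive bounds on acceptable report years.

    Returns
    -------
    pandas.DataFrame
        One row per reporting event; ``doses_administered`` and
        ``target_population`` use a nullable integer dtype so that absent
        cells stay missing rather than becoming 0.

    Raises
    ------
    PanelValidationError
        On malformed years or vaccines, duplicate (country, year, vaccine)
        keys, negative doses, or non-positive target populations.
    """
    df = pd.read_csv(
        path, dtype=str, keep_default_na=False, na_values=_NA_VALUES, skipinitialspace=True
    )
    _require_columns(df, REPORTED_COLUMNS, path)
    df = df[REPORTED_COLUMNS].copy()

    year = pd.to_numeric(df["year"], errors="coerce")
    if year.isna().any():
        row = int(df.index[year.isna()][0]) + 2  # header is line 1
        raise PanelValidationError(f"{path}: line {row}: unparseable year {df['year'][year.isna()].iloc[0]!r}")
    df["year"] = year.astype(int)
    lo, hi = year_range
    out_of_range = (df["year"] < lo) | (df["year"] > hi)
    if out_of_range.any():
        bad = df.loc[out_of_range, "year"].iloc[0]
        raise PanelValidationError(f"{path}: year {bad} outside configured range {lo}-{hi}")

    df["vaccine"] = df["vaccine"].str.strip().str.upper()
    bad_vax = ~df["vaccine"].isin(VACCINES)
    if bad_vax.any():
        raise PanelValidationError(
            f"{path}: unknown vaccine {df.loc[bad_vax, 'vaccine'].iloc[0]!r} (expected one of {VACCINES})"
        )

    dup = df.duplicated(subset=["country_code", "year", "vaccine"], keep=False)
    if dup.any():
        key = df.loc[dup, ["country_code", "year", "vaccine"]].iloc[0].tolist()
        raise PanelValidationError(f"{path}: duplicate reporting event for {tuple(key)}")

    for col in ("doses_administered", "target_population"):
        vals = pd.to_numeric(df[col], errors="coerce")
        unparsed = vals.isna() & df[col].notna()
        if unparsed.any():
            raise PanelValidationError(
                f"{path}: column {col!r}: unparseable value {df.loc[unparsed, col].iloc[0]!r}"
            )
        df[col] = vals.round().astype("Int64")

    neg = df["doses_administered"].notna() & (df["doses_administered"] < 0)
    if neg.any():
        raise PanelValidationError(f"{path}: negative doses_administered for "
                                   f"{tuple(df.loc[neg, ['country_code', 'year', 'vaccine']].iloc[0])}")
    nonpos = df["target_population"].notna() & (df["target_population"] <= 0)
    if nonpos.any():
        raise PanelValidationError(f"{path}: non-positive target_population for "
                                   f"{tuple(df.loc[nonpos, ['country_code', 'year', 'vaccine']].iloc[0])}")

    return df.sort_values(["country_code", "year", "vaccine"]).reset_index(drop=True)


def read_reference_panel(path, expected_grid: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read the reference (country, year) panel of live births and surviving infants.

    If ``expected_grid`` is given (a DataFrame with ``country_code`` and
    ``year`` columns, e.g. the reference-eligible portion of the event grid),
    the panel must cover it completely; gaps raise a completeness error
    naming the first missing cell.
    """
    df = pd.read_csv(
        path, dtype=str, keep_default_na=False, na_values=_NA_VALUES, skipinitialspace=True
    )
    _require_columns(df, REFERENCE_COLUMNS, path)
    df = df[REFERENCE_COLUMNS].copy()
    df["year"] = pd.to_numeric(df["year"], errors="raise").astype(int)
    for col in ("live_births", "surviving_infants"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[col].isna().any():
            raise PanelValidationError(f"{path}: missing or unparseable {col}")
        if (df[col] <= 0).any():
            bad = df.loc[df[col] <= 0].iloc[0]
            raise PanelValidationError(
                f"{path}: non-positive {col} for ({bad['country_code']}, {bad['year']})"
            )

    dup = df.duplicated(subset=["country_code", "year"], keep=False)
    if dup.any():
        key = df.loc[dup, ["country_code", "year"]].iloc[0].tolist()
        raise PanelValidationError(f"{path}: duplicate reference row for {tuple(key)}")

    inverted = df["surviving_infants"] > df["live_births"]
    if inverted.any():
        bad = df.loc[inverted].iloc[0]
        raise PanelValidationError(
            f"{path}: surviving_infants > live_births for ({bad['country_code']}, {int(bad['year'])})"
        )

    if expected_grid is not None:
        want = expected_grid[["country_code", "year"]].drop_duplicates()
        have = df[["country_code", "year"]]
        gaps = want.merge(have, how="left", indicator=True)
        gaps = gaps[gaps["_merge"] == "left_only"]
        if len(gaps):
            first = gaps.iloc[0]
            raise PanelValidationError(
                f"{path}: reference panel incomplete — {len(gaps)} missing cell(s), "
                f"first ({first['country_code']}, {int(first['year'])})"
            )

    return df.sort_values(["country_code", "year"]).reset_index(drop=True)


def read_country_meta(path) -> pd.DataFrame:
    """Read country metadata (region, start years, schedule eligibility flags)."""
    df = pd.read_csv(
        path, dtype=str, keep_default_na=False, na_values=_NA_VALUES, skipinitialspace=True
    )
    _require_columns(df, META_COLUMNS, path)
    cols = META_COLUMNS + [c for c in META_OPTIONAL_COLUMNS if c in df.columns]
    df = df[cols].copy()

    dup = df.duplicated(subset=["country_code"], keep=False)
    if dup.any():
        raise PanelValidationError(
            f"{path}: duplicate country {df.loc[dup, 'country_code'].iloc[0]!r}"
        )

    df["region"] = df["region"].str.strip().str.upper()
    bad = ~df["region"].isin(REGIONS)
    if bad.any():
        raise PanelValidationError(
            f"{path}: unknown region {df.loc[bad, 'region'].iloc[0]!r} "
            f"for {df.loc[bad, 'country_code'].iloc[0]!r} (expected one of {REGIONS})"
        )

    for col in ("membership_start_year", "first_reporting_year"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    if (df["first_reporting_year"] < df["membership_start_year"]).any():
        bad_row = df[df["first_reporting_year"] < df["membership_start_year"]].iloc[0]
        raise PanelValidationError(
            f"{path}: first_reporting_year precedes membership for {bad_row['country_code']!r}"
        )

    for col in META_COLUMNS[4:]:
        df[col] = _parse_bool(df[col], col, path)

    for col in META_OPTIONAL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].fillna("")
        else:
            df[col] = ""

    return df.sort_values("country_code").reset_index(drop=True)


def parse_year_overrides(cell: str) -> frozenset[int]:
    """Parse a ';'-separated per-year override cell into a set of years."""
    cell = (cell or "").strip()
    if not cell:
        return frozenset()
    return frozenset(int(tok) for tok in cell.split(";") if tok.strip())


def write_reported_panel(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep="")


def write_reference_panel(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_country_meta(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
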