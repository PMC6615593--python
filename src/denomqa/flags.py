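"""Derived statistics and the nine denominator accuracy/consistency flags.

Formulas (all carried at full floating precision; rounding happens only when
rendering reports):

* administrative coverage:      ``100 * doses / target``
* year-to-year difference:      ``100 * (value_year2 / value_year1 - 1)``
* difference vs reference:      ``100 * (reported - reference) / reference``
  (negative means the country reported fewer than the reference projects)
* implied infant mortality:     ``1000 * (LB - SI) / LB``
  (negative is infeasible — more surviving infants than live births)

The nine flags per included country-year:

======  =======================================================
F1      reported live births (BCG target) missing
F2      reported surviving infants (DTP3 target) missing
F3      |year-to-year difference| of reported LB or SI > 10%
F4      |year-to-year difference| of BCG or DTP3 coverage > 10%
F5      reported BCG or DTP3 coverage > 100%
F6      negative implied infant mortality rate
F7      |difference of reported LB vs reference LB| > 10%
F8      |difference of reported SI vs reference SI| > 10%
F9      DTP3 target population differs from DTP1 target
======  =======================================================

All thresholds are strict inequalities; boundary values do not fire.  A flag
whose inputs are missing (or whose prior year is missing or ineligible, for
the year-to-year flags) is recorded as non-evaluable rather than unfired.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
import yaml

FLAG_IDS = (
    "F1_LB_MISSING",
    "F2_SI_MISSING",
    "F3_YOY_DENOM_GT10",
    "F4_YOY_COV_GT10",
    "F5_COV_GT100",
    "F6_NEG_IMR",
    "F7_LB_REF_DIFF_GT10",
    "F8_SI_REF_DIFF_GT10",
    "F9_DTP3_NE_DTP1",
)

FLAG_COLUMNS = [
    "country_code", "year", "flag_id", "evaluable", "fired", "statistic_value", "threshold",
]

#: Table-style indicator identifiers (finer grain than the nine flags: the
#: combined fluctuation flags F3/F4 are split into their component series and
#: tallied at both an auxiliary and the flagging threshold).
INDICATOR_IDS = (
    "lb_missing",
    "si_missing",
    "yoy_lb",
    "yoy_si",
    "yoy_cov_bcg",
    "yoy_cov_dtp3",
    "cov_bcg_gt100",
    "cov_dtp3_gt100",
    "neg_imr",
    "lb_ref_diff",
    "si_ref_diff",
    "dtp_mismatch",
)


@dataclass(frozen=True)
class Thresholds:
    """Flagging thresholds, in percent.

    ``aux_yoy_pct`` is the auxiliary fluctuation threshold used only in the
    indicator tallies; the flag itself uses ``denom_yoy_pct``/``cov_yoy_pct``.
    """

    denom_yoy_pct: float = 10.0
    cov_yoy_pct: float = 10.0
    ref_diff_pct: float = 10.0
    aux_yoy_pct: float = 5.0
    coverage_cap_pct: float = 100.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "Thresholds":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown threshold key(s) {sorted(unknown)}")
        return cls(**raw)


def _as_float(x):
    """Coerce scalars/arrays to float with NaN for missing; keeps shape."""
    arr = pd.array(np.atleast_1d(x), dtype="Float64").to_numpy(dtype=float, na_value=np.nan)
    return arr if np.ndim(x) else arr[0]


def coverage(doses, target_population):
    """Administrative coverage in percent: ``100 * doses / target``.

    Missing inputs propagate to a missing result; a non-positive target is an
    error (a zero target is invalid data, not a zero-coverage report).
    """
    d, t = _as_float(doses), _as_float(target_population)
    if np.any(~np.isnan(t) & (t <= 0)):
        raise ValueError("target_population must be positive")
    if np.any(~np.isnan(d) & (d < 0)):
        raise ValueError("doses must be nonnegative")
    return 100.0 * d / t


def yoy_percent_difference(value_year1, value_year2):
    """Year-to-year percent difference ``100 * (year2 / year1 - 1)``.

    Applies identically to denominator series and to coverage series.
    """
    v1, v2 = _as_float(value_year1), _as_float(value_year2)
    if np.any(~np.isnan(v1) & (v1 <= 0)):
        raise ValueError("year-1 value must be positive")
    return 100.0 * (v2 / v1 - 1.0)


def percent_difference_vs_reference(reported, reference):
    """Signed percent difference of a reported value from its reference.

    Negative means the reported value is below the reference projection.
    """
    rep, ref = _as_float(reported), _as_float(reference)
    if np.any(~np.isnan(ref) & (ref <= 0)):
        raise ValueError("reference value must be positive")
    return 100.0 * (rep - ref) / ref


def implied_imr(live_births, surviving_infants):
    """Implied infant mortality rate per 1000: ``1000 * (LB - SI) / LB``.

    Computed from a country's own reported denominators for the same year;
    negative values (SI > LB) are infeasible and flag inconsistency.
    """
    lb, si = _as_float(live_births), _as_float(surviving_infants)
    if np.any(~np.isnan(lb) & (lb <= 0)):
        raise ValueError("live_births must be positive")
    return 1000.0 * (lb - si) / lb


def coverage_error_from_denominator_error(true_coverage, relative_denominator_error):
    """Coverage error (percentage points) induced by a denominator error.

    If the true target population is understated by a relative error ``e``
    (e.g. ``e = -0.10`` for a 10% underestimate), measured coverage becomes
    ``true / (1 + e)``; the returned error is measured minus true coverage.
    The error grows with coverage, which is why denominator quality matters
    most in high-coverage programs.
    """
    c, e = _as_float(true_coverage), _as_float(relative_denominator_error)
    if np.any(~np.isnan(e) & (e <= -1)):
        raise ValueError("relative denominator error must exceed -1")
    if np.any(~np.isnan(c) & (c < 0)):
        raise ValueError("true coverage must be nonnegative")
    return c / (1.0 + e) - c


# ---------------------------------------------------------------------------
# panel-level derived statistics


def _event_values(reports: pd.DataFrame, vaccine: str) -> pd.DataFrame:
    sub = reports.loc[reports["vaccine"] == vaccine,
                      ["country_code", "year", "doses_administered", "target_population"]]
    return sub.set_index(["country_code", "year"])


def compute_derived_statistics(
    reports: pd.DataFrame, reference: pd.DataFrame, decisions: pd.DataFrame
) -> pd.DataFrame:
    """Per (country, year) statistics over the included analysis set.

    ``decisions`` is the concatenated eligibility ledger for BCG and DTP3;
    values belonging to excluded events are treated as absent, so every
    downstream statistic is missing exactly when an input is missing or
    ineligible.  Year-to-year differences require two consecutive eligible,
    non-missing years and never bridge gaps.
    """
    bcg_dec = decisions[decisions["vaccine"] == "BCG"].set_index(["country_code", "year"])
    dtp3_dec = decisions[decisions["vaccine"] == "DTP3"].set_index(["country_code", "year"])

    # spine: the union grid of both vaccines' decisions, one row per cell
    spine = (
        decisions[["country_code", "year"]]
        .drop_duplicates()
        .sort_values(["country_code", "year"])
        .reset_index(drop=True)
    )
    idx = pd.MultiIndex.from_frame(spine)

    stats = spine.copy()
    stats["bcg_included"] = bcg_dec["included"].reindex(idx, fill_value=False).to_numpy()
    stats["dtp3_included"] = dtp3_dec["included"].reindex(idx, fill_value=False).to_numpy()

    bcg = _event_values(reports, "BCG").reindex(idx)
    dtp3 = _event_values(reports, "DTP3").reindex(idx)
    dtp1 = _event_values(reports, "DTP1").reindex(idx)

    def eligible(series, mask):
        vals = series.to_numpy(dtype=float, na_value=np.nan)
        return np.where(mask, vals, np.nan)

    stats["lb"] = eligible(bcg["target_population"], stats["bcg_included"])
    stats["doses_bcg"] = eligible(bcg["doses_administered"], stats["bcg_included"])
    stats["si"] = eligible(dtp3["target_population"], stats["dtp3_included"])
    stats["doses_dtp3"] = eligible(dtp3["doses_administered"], stats["dtp3_included"])
    stats["dtp1_target"] = eligible(dtp1["target_population"], stats["dtp3_included"])

    stats["coverage_bcg"] = coverage(stats["doses_bcg"], stats["lb"])
    stats["coverage_dtp3"] = coverage(stats["doses_dtp3"], stats["si"])

    def yoy(col):
        grouped = stats.groupby("country_code", sort=False)
        prev = grouped[col].shift(1)
        prev_year = grouped["year"].shift(1)
        consecutive = (stats["year"] - prev_year) == 1
        prev = prev.where(consecutive)
        return yoy_percent_difference(prev, stats[col])

    stats["yoy_diff_lb"] = yoy("lb")
    stats["yoy_diff_si"] = yoy("si")
    stats["yoy_diff_cov_bcg"] = yoy("coverage_bcg")
    stats["yoy_diff_cov_dtp3"] = yoy("coverage_dtp3")

    ref = reference.set_index(["country_code", "year"]).reindex(idx)
    stats["ref_lb"] = np.where(stats["bcg_included"],
                               ref["live_births"].to_numpy(dtype=float, na_value=np.nan), np.nan)
    stats["ref_si"] = np.where(stats["dtp3_included"],
                               ref["surviving_infants"].to_numpy(dtype=float, na_value=np.nan), np.nan)
    stats["pct_diff_lb_vs_ref"] = percent_difference_vs_reference(stats["lb"], stats["ref_lb"])
    stats["pct_diff_si_vs_ref"] = percent_difference_vs_reference(stats["si"], stats["ref_si"])

    stats["implied_imr"] = implied_imr(stats["lb"], stats["si"])
    return stats


def _exceeds(values, threshold) -> np.ndarray:
    """Strictly greater, robust to float round-off at the boundary.

    Ratios such as 1100/1000 carry ~1e-16 relative error, which must not tip
    an exactly-at-threshold statistic over a strict ``>`` rule; values within
    1e-9 relative of the threshold are treated as equal to it.
    """
    v = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        return (v > threshold) & ~np.isclose(v, threshold, rtol=1e-9, atol=1e-12)


def _max_abs_signed(frame: pd.DataFrame) -> pd.Series:
    """Row-wise signed value with the largest magnitude (NaN if all missing)."""
    arr = frame.to_numpy(dtype=float)
    absarr = np.abs(arr)
    allnan = np.all(np.isnan(arr), axis=1)
    pick = np.nanargmax(np.where(np.isnan(absarr), -np.inf, absarr), axis=1)
    out = arr[np.arange(len(arr)), pick]
    out[allnan] = np.nan
    return pd.Series(out, index=frame.index)


def evaluate_flags(
    reports: pd.DataFrame,
    reference: pd.DataFrame,
    decisions: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Evaluate the nine flags for every country-year in the analysis set.

    Returns a long DataFrame with one row per (country, year, flag), carrying
    ``evaluable``, ``fired``, the underlying signed statistic and the
    threshold applied.  Country-years excluded for both vaccines receive no
    rows.
    """
    stats = compute_derived_statistics(reports, reference, decisions)
    return evaluate_flags_from_stats(stats, thresholds)


def evaluate_flags_from_stats(stats: pd.DataFrame, thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Flag evaluation over a precomputed derived-statistics panel."""
    s = stats[stats["bcg_included"] | stats["dtp3_included"]].reset_index(drop=True)
    n = len(s)
    th = thresholds
    records = []

    def add(flag_id, evaluable, fired, statistic, threshold):
        rec = pd.DataFrame({
            "country_code": s["country_code"],
            "year": s["year"],
            "flag_id": flag_id,
            "evaluable": np.asarray(evaluable, dtype=bool),
            "fired": np.asarray(fired, dtype=bool) & np.asarray(evaluable, dtype=bool),
            "statistic_value": np.asarray(statistic, dtype=float) if statistic is not None else np.nan,
            "threshold": threshold if threshold is not None else np.nan,
        })
        records.append(rec)

    lb_missing = s["bcg_included"] & s["lb"].isna()
    add("F1_LB_MISSING", s["bcg_included"], lb_missing, None, None)

    si_missing = s["dtp3_included"] & s["si"].isna()
    add("F2_SI_MISSING", s["dtp3_included"], si_missing, None, None)

    yoy_denom = s[["yoy_diff_lb", "yoy_diff_si"]]
    f3_eval = yoy_denom.notna().any(axis=1)
    f3_fire = _exceeds(yoy_denom.abs(), th.denom_yoy_pct).any(axis=1)
    add("F3_YOY_DENOM_GT10", f3_eval, f3_fire, _max_abs_signed(yoy_denom), th.denom_yoy_pct)

    yoy_cov = s[["yoy_diff_cov_bcg", "yoy_diff_cov_dtp3"]]
    f4_eval = yoy_cov.notna().any(axis=1)
    f4_fire = _exceeds(yoy_cov.abs(), th.cov_yoy_pct).any(axis=1)
    add("F4_YOY_COV_GT10", f4_eval, f4_fire, _max_abs_signed(yoy_cov), th.cov_yoy_pct)

    cov = s[["coverage_bcg", "coverage_dtp3"]]
    f5_eval = cov.notna().any(axis=1)
    f5_fire = _exceeds(cov, th.coverage_cap_pct).any(axis=1)
    add("F5_COV_GT100", f5_eval, f5_fire, cov.max(axis=1), th.coverage_cap_pct)

    f6_eval = s["implied_imr"].notna()
    f6_fire = s["implied_imr"] < 0
    add("F6_NEG_IMR", f6_eval, f6_fire, s["implied_imr"], 0.0)

    f7_eval = s["pct_diff_lb_vs_ref"].notna()
    f7_fire = _exceeds(s["pct_diff_lb_vs_ref"].abs(), th.ref_diff_pct)
    add("F7_LB_REF_DIFF_GT10", f7_eval, f7_fire, s["pct_diff_lb_vs_ref"], th.ref_diff_pct)

    f8_eval = s["pct_diff_si_vs_ref"].notna()
    f8_fire = _exceeds(s["pct_diff_si_vs_ref"].abs(), th.ref_diff_pct)
    add("F8_SI_REF_DIFF_GT10", f8_eval, f8_fire, s["pct_diff_si_vs_ref"], th.ref_diff_pct)

    f9_eval = s["dtp3_included"] & s["si"].notna() & s["dtp1_target"].notna()
    f9_fire = f9_eval & (s["si"] != s["dtp1_target"])
    add("F9_DTP3_NE_DTP1", f9_eval, f9_fire, s["si"] - s["dtp1_target"], 0.0)

    flags = pd.concat(records, ignore_index=True)
    flags["statistic_value"] = flags["statistic_value"].where(flags["evaluable"])
    return flags.sort_values(["country_code", "year", "flag_id"]).reset_index(drop=True)[FLAG_COLUMNS]


def evaluate_indicators(stats: pd.DataFrame, thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Component-level indicator records for the summary tables.

    Finer grained than the nine flags: each fluctuation series (reported LB,
    reported SI, BCG coverage, DTP3 coverage) is tallied separately and at
    both the auxiliary and the flagging threshold.  Returns a long DataFrame
    with columns country_code, year, indicator, threshold_variant, evaluable,
    fired, value.
    """
    s = stats[stats["bcg_included"] | stats["dtp3_included"]].reset_index(drop=True)
    th = thresholds
    out = []

    def add(indicator, variant, evaluable, fired, value):
        out.append(pd.DataFrame({
            "country_code": s["country_code"],
            "year": s["year"],
            "indicator": indicator,
            "threshold_variant": variant,
            "evaluable": np.asarray(evaluable, dtype=bool),
            "fired": np.asarray(fired, dtype=bool) & np.asarray(evaluable, dtype=bool),
            "value": np.asarray(value, dtype=float) if value is not None else np.nan,
        }))

    add("lb_missing", np.nan, s["bcg_included"], s["bcg_included"] & s["lb"].isna(), None)
    add("si_missing", np.nan, s["dtp3_included"], s["dtp3_included"] & s["si"].isna(), None)

    for ind, col, _thr in (
        ("yoy_lb", "yoy_diff_lb", th.denom_yoy_pct),
        ("yoy_si", "yoy_diff_si", th.denom_yoy_pct),
        ("yoy_cov_bcg", "yoy_diff_cov_bcg", th.cov_yoy_pct),
        ("yoy_cov_dtp3", "yoy_diff_cov_dtp3", th.cov_yoy_pct),
    ):
        for variant in (th.aux_yoy_pct, _thr):
            add(ind, variant, s[col].notna(), _exceeds(s[col].abs(), variant), s[col])

    add("cov_bcg_gt100", th.coverage_cap_pct, s["coverage_bcg"].notna(),
        _exceeds(s["coverage_bcg"], th.coverage_cap_pct), s["coverage_bcg"])
    add("cov_dtp3_gt100", th.coverage_cap_pct, s["coverage_dtp3"].notna(),
        _exceeds(s["coverage_dtp3"], th.coverage_cap_pct), s["coverage_dtp3"])
    add("neg_imr", 0.0, s["implied_imr"].notna(), s["implied_imr"] < 0, s["implied_imr"])
    add("lb_ref_diff", th.ref_diff_pct, s["pct_diff_lb_vs_ref"].notna(),
        _exceeds(s["pct_diff_lb_vs_ref"].abs(), th.ref_diff_pct), s["pct_diff_lb_vs_ref"])
    add("si_ref_diff", th.ref_diff_pct, s["pct_diff_si_vs_ref"].notna(),
        _exceeds(s["pct_diff_si_vs_ref"].abs(), th.ref_diff_pct), s["pct_diff_si_vs_ref"])

    f9_eval = s["dtp3_included"] & s["si"].notna() & s["dtp1_target"].notna()
    add("dtp_mismatch", np.nan, f9_eval, f9_eval & (s["si"] != s["dtp1_target"]),
        s["si"] - s["dtp1_target"])

    ind = pd.concat(out, ignore_index=True)
    ind["value"] = ind["value"].where(ind["evaluable"])
    return ind


def write_flags(flags: pd.DataFrame, path) -> None:
    flags.to_csv(path, index=False)


def read_flags(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"country_code": str, "flag_id": str})
    df["year"] = df["year"].astype(int)
    for col in ("evaluable", "fired"):
        df[col] = df[col].astype(bool)
    return df[FLAG_COLUMNS]
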