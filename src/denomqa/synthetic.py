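"""Seeded synthetic panels with planted anomalies and a truth ledger.

The generator first builds a *clean* panel: per country, reference live
births follow smooth multiplicative growth, reference surviving infants are
``LB * (1 - IMR/1000)`` for a country-level infant mortality rate, reported
denominators equal the (rounded) reference values, the DTP1 target equals
the DTP3 target, and doses equal ``coverage * target / 100`` for country-level
true coverage below 100%.  A clean panel therefore fires zero flags.

Anomalies are then planted cell by cell, in a documented draw order
(countries, then years, then anomaly kinds), each entered in a truth ledger.
Planting is surgical: ancillary quantities are co-scaled so that each
planted anomaly fires its own flag with a magnitude bounded away from the
threshold, while mechanically unavoidable knock-ons (a denominator jump in
year *t* necessarily diverges from the smooth reference in *t* and reverts in
*t+1*) are declared in a per-kind *induced* map used by the recovery scorer.
At most one anomaly is planted per country within any three consecutive
years, so plantings never interact; attempts falling in an occupied window
are skipped and do not enter the ledger.

Anomaly kinds and the flags they must fire:

====================  ==========================================
missing_lb            F1 (BCG target removed; doses kept)
missing_si            F2 (DTP3 target removed; doses kept)
denom_jump_gt10       F3 (one-year spike of LB, SI and DTP1
                      targets together, doses co-scaled)
coverage_gt100        F5 and F4 (BCG doses raised above target)
negative_imr          F6 (reported SI set above reported LB)
ref_divergence_gt10   F7 and F8 (all reported values scaled by a
                      common factor away from the reference)
dtp_mismatch          F9 (DTP1 target offset from DTP3 target)
====================  ==========================================

The module also provides deterministic *study-scale* builders: metadata for
a synthetic 194-country, 2000-2016 panel whose inclusion cascade reproduces
the reference tallies (3,298 grid events; 2,565 included BCG events across
153 countries; 2,939 DTP3 events across 174), plus exact-count planting
helpers for missingness and reference divergence.  All country codes are
synthetic (AAA, AAB, ...), not real ISO3 assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from denomqa.eligibility import apply_eligibility, build_event_grid
from denomqa.ingest import META_COLUMNS, META_OPTIONAL_COLUMNS, REPORTED_COLUMNS

ANOMALY_KINDS = (
    "missing_lb",
    "missing_si",
    "denom_jump_gt10",
    "coverage_gt100",
    "negative_imr",
    "ref_divergence_gt10",
    "dtp_mismatch",
)

#: flags each anomaly kind must fire, as (flag_id, year offset)
EXPECTED_FLAGS = {
    "missing_lb": (("F1_LB_MISSING", 0),),
    "missing_si": (("F2_SI_MISSING", 0),),
    "denom_jump_gt10": (("F3_YOY_DENOM_GT10", 0),),
    "coverage_gt100": (("F5_COV_GT100", 0), ("F4_YOY_COV_GT10", 0)),
    "negative_imr": (("F6_NEG_IMR", 0),),
    "ref_divergence_gt10": (("F7_LB_REF_DIFF_GT10", 0), ("F8_SI_REF_DIFF_GT10", 0)),
    "dtp_mismatch": (("F9_DTP3_NE_DTP1", 0),),
}

#: flags each anomaly kind may legitimately also fire (induced, not false)
INDUCED_FLAGS = {
    "missing_lb": (),
    "missing_si": (),
    "denom_jump_gt10": (
        ("F3_YOY_DENOM_GT10", 1),
        ("F7_LB_REF_DIFF_GT10", 0),
        ("F8_SI_REF_DIFF_GT10", 0),
        ("F4_YOY_COV_GT10", 0),
        ("F4_YOY_COV_GT10", 1),
    ),
    "coverage_gt100": (("F4_YOY_COV_GT10", 1),),
    "negative_imr": (
        ("F3_YOY_DENOM_GT10", 0),
        ("F3_YOY_DENOM_GT10", 1),
        ("F8_SI_REF_DIFF_GT10", 0),
    ),
    "ref_divergence_gt10": (("F3_YOY_DENOM_GT10", 0), ("F3_YOY_DENOM_GT10", 1)),
    "dtp_mismatch": (),
}

_REGION_COUNTS = {"AFR": 47, "AMR": 35, "EMR": 21, "EUR": 53, "SEAR": 11, "WPR": 27}


def _default_rates() -> dict[str, float]:
    # per-country-year planting probabilities, in the neighbourhood of the
    # per-flag prevalences seen in real national reporting (roughly 5-15% for
    # most flags, with reference divergence the most common)
    return {
        "missing_lb": 0.04,
        "missing_si": 0.04,
        "denom_jump_gt10": 0.06,
        "coverage_gt100": 0.05,
        "negative_imr": 0.04,
        "ref_divergence_gt10": 0.10,
        "dtp_mismatch": 0.05,
    }


def _default_magnitudes() -> dict[str, tuple[float, float]]:
    return {
        "denom_jump_gt10": (15.0, 50.0),      # percent jump, either sign
        "coverage_gt100": (115.0, 145.0),     # resulting coverage percent
        "negative_imr": (1.02, 1.15),         # reported SI as multiple of LB
        "ref_divergence_gt10": (15.0, 60.0),  # percent divergence, either sign
        "dtp_mismatch": (0.05, 0.20),         # relative DTP1 target offset
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic panel generator.

    Magnitude ranges must sit strictly beyond the corresponding flag
    thresholds by at least ``magnitude_margin_pct`` percentage points, so
    that planted anomalies are unambiguously recoverable.
    """

    n_countries: int = 194
    year_range: tuple[int, int] = (2000, 2016)
    region_proportions: dict[str, int] = field(default_factory=lambda: dict(_REGION_COUNTS))
    baseline_lb: tuple[float, float] = (20_000.0, 5_000_000.0)
    imr_per_1000: tuple[float, float] = (2.0, 80.0)
    true_coverage: tuple[float, float] = (60.0, 99.0)
    growth_rate: tuple[float, float] = (0.002, 0.030)
    anomaly_rates: dict[str, float] = field(default_factory=_default_rates)
    anomaly_magnitudes: dict[str, tuple[float, float]] = field(default_factory=_default_magnitudes)
    magnitude_margin_pct: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ValueError("n_countries must be positive")
        lo, hi = self.year_range
        if hi < lo:
            raise ValueError("empty year range")
        for kind, rate in self.anomaly_rates.items():
            if kind not in ANOMALY_KINDS:
                raise ValueError(f"unknown anomaly kind {kind!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"anomaly rate for {kind} must be in [0, 1]")
        if self.magnitude_margin_pct < 2.0:
            raise ValueError("magnitude margin must be at least 2 percentage points")
        mags = self.anomaly_magnitudes
        floor = 10.0 + self.magnitude_margin_pct
        if mags["denom_jump_gt10"][0] < floor:
            raise ValueError(f"denominator jump magnitudes must start above {floor}%")
        if mags["ref_divergence_gt10"][0] < floor:
            raise ValueError(f"reference divergence magnitudes must start above {floor}%")
        if mags["coverage_gt100"][0] < 100.0 + self.magnitude_margin_pct:
            raise ValueError("planted coverage must exceed 100% by the margin")
        if mags["negative_imr"][0] <= 1.0:
            raise ValueError("negative-IMR factor must exceed 1 (SI strictly above LB)")
        if self.growth_rate[1] * 100 >= 10.0 - self.magnitude_margin_pct:
            raise ValueError("baseline growth must stay clear of the fluctuation threshold")
        if self.true_coverage[1] >= 100.0 or self.true_coverage[0] <= 0.0:
            raise ValueError("true coverage must lie strictly inside (0, 100)")


def _country_codes(n: int) -> list[str]:
    """Synthetic three-letter codes AAA, AAB, ... (not real ISO3 assignments)."""
    if n > 26**3:
        raise ValueError("too many countries for three-letter codes")
    return [
        chr(65 + i // 676) + chr(65 + (i // 26) % 26) + chr(65 + i % 26)
        for i in range(n)
    ]


def _assign_regions(n: int, proportions: dict[str, int]) -> list[str]:
    """Deterministic largest-remainder allocation of countries to regions."""
    total = sum(proportions.values())
    quotas = {r: n * w / total for r, w in proportions.items()}
    counts = {r: int(q) for r, q in quotas.items()}
    shortfall = n - sum(counts.values())
    by_remainder = sorted(proportions, key=lambda r: quotas[r] - counts[r], reverse=True)
    for r in by_remainder[:shortfall]:
        counts[r] += 1
    out: list[str] = []
    for r in sorted(counts):
        out.extend([r] * counts[r])
    return out


def _fully_eligible_meta(codes: list[str], regions: list[str], year0: int) -> pd.DataFrame:
    meta = pd.DataFrame({
        "country_code": codes,
        "region": regions,
        "membership_start_year": year0,
        "first_reporting_year": year0,
        "has_reference_estimates": True,
        "bcg_in_schedule": True,
        "bcg_target_is_full_birth_cohort": True,
        "bcg_target_age_under_one": True,
        "dtp3_target_age_under_one": True,
        "ever_reported_bcg_target": True,
        "ever_reported_dtp3_target": True,
    })
    for col in META_OPTIONAL_COLUMNS:
        meta[col] = ""
    return meta


class _Panel:
    """Mutable per-country arrays during generation, keyed (country, year)."""

    def __init__(self, codes, years):
        self.codes = codes
        self.years = list(years)
        n, t = len(codes), len(self.years)
        shape = (n, t)
        self.ref_lb = np.zeros(shape)
        self.ref_si = np.zeros(shape)
        self.lb = np.zeros(shape)          # reported BCG target
        self.si = np.zeros(shape)          # reported DTP3 target
        self.dtp1 = np.zeros(shape)        # reported DTP1 target
        self.doses_bcg = np.zeros(shape)
        self.doses_dtp3 = np.zeros(shape)
        self.doses_dtp1 = np.zeros(shape)
        self.lb_missing = np.zeros(shape, dtype=bool)
        self.si_missing = np.zeros(shape, dtype=bool)


def _build_clean_panel(config: GeneratorConfig, rng: np.random.Generator,
                       codes: list[str]) -> _Panel:
    lo_y, hi_y = config.year_range
    years = range(lo_y, hi_y + 1)
    panel = _Panel(codes, years)
    n_years = len(panel.years)

    log_lo, log_hi = np.log(config.baseline_lb[0]), np.log(config.baseline_lb[1])
    for i in range(len(codes)):
        lb0 = float(np.exp(rng.uniform(log_lo, log_hi)))
        imr = rng.uniform(*config.imr_per_1000)
        cov_bcg = rng.uniform(*config.true_coverage)
        cov_dtp3 = rng.uniform(*config.true_coverage)
        cov_dtp1 = rng.uniform(*config.true_coverage)
        growth = rng.uniform(config.growth_rate[0], config.growth_rate[1], size=n_years - 1)
        ref_lb = lb0 * np.concatenate([[1.0], np.cumprod(1.0 + growth)])
        panel.ref_lb[i] = ref_lb
        panel.ref_si[i] = ref_lb * (1.0 - imr / 1000.0)
        panel.lb[i] = np.round(panel.ref_lb[i])
        panel.si[i] = np.round(panel.ref_si[i])
        panel.dtp1[i] = panel.si[i]
        panel.doses_bcg[i] = np.round(cov_bcg * panel.lb[i] / 100.0)
        panel.doses_dtp3[i] = np.round(cov_dtp3 * panel.si[i] / 100.0)
        panel.doses_dtp1[i] = np.round(cov_dtp1 * panel.dtp1[i] / 100.0)
    return panel


def _plant(panel: _Panel, kind: str, i: int, t: int,
           config: GeneratorConfig, rng: np.random.Generator) -> float:
    """Apply one anomaly at country index ``i``, year index ``t``.

    Returns the planted value recorded in the truth ledger.
    """
    mags = config.anomaly_magnitudes
    if kind == "missing_lb":
        panel.lb_missing[i, t] = True
        return np.nan
    if kind == "missing_si":
        panel.si_missing[i, t] = True
        return np.nan
    if kind == "denom_jump_gt10":
        pct = rng.uniform(*mags["denom_jump_gt10"]) * rng.choice([-1.0, 1.0])
        factor = 1.0 + pct / 100.0
        for arr in (panel.lb, panel.si, panel.dtp1,
                    panel.doses_bcg, panel.doses_dtp3, panel.doses_dtp1):
            arr[i, t] = np.round(arr[i, t] * factor)
        return pct
    if kind == "coverage_gt100":
        cov = rng.uniform(*mags["coverage_gt100"])
        panel.doses_bcg[i, t] = np.round(cov * panel.lb[i, t] / 100.0)
        return cov
    if kind == "negative_imr":
        factor = rng.uniform(*mags["negative_imr"])
        new_si = np.round(panel.lb[i, t] * factor)
        old_cov_dtp3 = 100.0 * panel.doses_dtp3[i, t] / panel.si[i, t]
        old_cov_dtp1 = 100.0 * panel.doses_dtp1[i, t] / panel.dtp1[i, t]
        panel.si[i, t] = new_si
        panel.dtp1[i, t] = new_si
        panel.doses_dtp3[i, t] = np.round(old_cov_dtp3 * new_si / 100.0)
        panel.doses_dtp1[i, t] = np.round(old_cov_dtp1 * new_si / 100.0)
        return 1000.0 * (panel.lb[i, t] - new_si) / panel.lb[i, t]
    if kind == "ref_divergence_gt10":
        pct = rng.uniform(*mags["ref_divergence_gt10"]) * rng.choice([-1.0, 1.0])
        factor = 1.0 + pct / 100.0
        for arr in (panel.lb, panel.si, panel.dtp1,
                    panel.doses_bcg, panel.doses_dtp3, panel.doses_dtp1):
            arr[i, t] = np.round(arr[i, t] * factor)
        return pct
    if kind == "dtp_mismatch":
        rel = rng.uniform(*mags["dtp_mismatch"]) * rng.choice([-1.0, 1.0])
        offset = np.round(panel.si[i, t] * rel)
        if offset == 0:
            offset = 1.0
        panel.dtp1[i, t] = panel.si[i, t] + offset
        return offset
    raise ValueError(f"unknown anomaly kind {kind!r}")


def _plant_anomalies(panel: _Panel, config: GeneratorConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    n, t_max = len(panel.codes), len(panel.years)
    occupied = np.zeros((n, t_max), dtype=bool)
    entries = []
    for i in range(n):
        for t in range(t_max):
            for kind in ANOMALY_KINDS:
                rate = config.anomaly_rates.get(kind, 0.0)
                u = rng.random()  # always drawn, keeping the stream aligned
                if u >= rate:
                    continue
                window = occupied[i, max(0, t - 1): t + 2]
                if window.any():
                    continue  # plantings never interact
                if kind in ("denom_jump_gt10", "coverage_gt100") and t == 0:
                    continue  # year-to-year evidence needs a prior-year value
                value = _plant(panel, kind, i, t, config, rng)
                occupied[i, t] = True
                entries.append({
                    "country_code": panel.codes[i],
                    "year": panel.years[t],
                    "anomaly_kind": kind,
                    "planted_value": value,
                })
    return pd.DataFrame(entries, columns=["country_code", "year", "anomaly_kind", "planted_value"])


def _panel_to_frames(panel: _Panel) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    for i, code in enumerate(panel.codes):
        for t, year in enumerate(panel.years):
            lb = pd.NA if panel.lb_missing[i, t] else int(panel.lb[i, t])
            si = pd.NA if panel.si_missing[i, t] else int(panel.si[i, t])
            rows.append((code, year, "BCG", int(panel.doses_bcg[i, t]), lb))
            rows.append((code, year, "DTP1", int(panel.doses_dtp1[i, t]), int(panel.dtp1[i, t])))
            rows.append((code, year, "DTP3", int(panel.doses_dtp3[i, t]), si))
    reports = pd.DataFrame(rows, columns=REPORTED_COLUMNS)
    for col in ("doses_administered", "target_population"):
        reports[col] = reports[col].astype("Int64")

    ref_rows = []
    for i, code in enumerate(panel.codes):
        for t, year in enumerate(panel.years):
            ref_rows.append((code, year, panel.ref_lb[i, t], panel.ref_si[i, t]))
    reference = pd.DataFrame(
        ref_rows, columns=["country_code", "year", "live_births", "surviving_infants"]
    )
    return reports, reference


def generate_panel(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (reports, reference, meta, truth_ledger) for one seed.

    Identical configs (including seed) produce identical output.  All
    countries are fully eligible; anomalies are planted in reported values
    only, so the reference panel always satisfies SI <= LB.
    """
    rng = np.random.default_rng(config.seed)
    codes = _country_codes(config.n_countries)
    regions = _assign_regions(config.n_countries, config.region_proportions)
    meta = _fully_eligible_meta(codes, regions, config.year_range[0])
    panel = _build_clean_panel(config, rng, codes)
    truth = _plant_anomalies(panel, config, rng)
    reports, reference = _panel_to_frames(panel)
    return reports, reference, meta, truth


# ---------------------------------------------------------------------------
# recovery scoring


def score_recovery(flags: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Precision/recall of flag firings against the truth ledger.

    A planting is *recovered* when every flag its kind must fire did fire at
    the planted (country, year).  For precision, fired events of a kind's
    primary flag(s) are counted false only when no planting's expected or
    induced set explains them (a jump, for instance, legitimately fires the
    following year's pair and the same year's reference comparison).
    Undefined ratios (no plantings, or nothing fired and nothing planted)
    are reported as NaN.
    """
    fired_cells: dict[str, set[tuple[str, int]]] = {}
    for flag_id, grp in flags[flags["fired"]].groupby("flag_id"):
        fired_cells[flag_id] = set(zip(grp["country_code"], grp["year"]))

    explained: dict[str, set[tuple[str, int]]] = {}
    for row in truth.itertuples(index=False):
        for flag_id, off in (
            EXPECTED_FLAGS[row.anomaly_kind] + INDUCED_FLAGS[row.anomaly_kind]
        ):
            explained.setdefault(flag_id, set()).add((row.country_code, row.year + off))

    rows = []
    for kind in ANOMALY_KINDS:
        planted = truth[truth["anomaly_kind"] == kind]
        n_planted = len(planted)
        expected = EXPECTED_FLAGS[kind]
        n_recovered = 0
        for row in planted.itertuples(index=False):
            if all((row.country_code, row.year + off) in fired_cells.get(f, set())
                   for f, off in expected):
                n_recovered += 1

        primary_flags = {f for f, off in expected if off == 0}
        n_true = 0
        n_false = 0
        for f in primary_flags:
            for cell in fired_cells.get(f, set()):
                if cell in set(zip(planted["country_code"], planted["year"])):
                    n_true += 1
                elif cell not in explained.get(f, set()):
                    n_false += 1

        recall = n_recovered / n_planted if n_planted else np.nan
        precision = n_true / (n_true + n_false) if (n_true + n_false) else np.nan
        rows.append({
            "anomaly_kind": kind,
            "n_planted": n_planted,
            "n_recovered": n_recovered,
            "recall": recall,
            "n_false_positive": n_false,
            "precision": precision,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study-scale builders (synthetic stand-ins for the real reporting universe)


def make_study_metadata(year_range: tuple[int, int] = (2000, 2016)) -> pd.DataFrame:
    """Synthetic 194-country metadata reproducing the inclusion-cascade tallies.

    The layout (all codes synthetic): 3 late joiners first reporting in 2006,
    2011 and 2002 (19 pre-reporting events); 10 countries without reference
    estimates (170 events); 31 countries excluded from the BCG analysis for
    schedule/cohort/age/never-reported reasons (527 events) of which 10 are
    also excluded from DTP3 (170 events); and 2 otherwise-included countries
    with per-year BCG schedule overrides totalling 17 events, bringing the
    BCG-specific exclusions to 544.  Applying the cascade yields 2,565
    included BCG events across 153 countries and 2,939 included DTP3 events
    across 174 countries out of the 3,298-cell grid.
    """
    n = 194
    codes = _country_codes(n)
    regions = _assign_regions(n, dict(_REGION_COUNTS))
    meta = _fully_eligible_meta(codes, regions, year_range[0])

    # late joiners: first reporting years as in the 2000-2016 reporting record
    for idx, year in zip((0, 1, 2), (2006, 2011, 2002)):
        meta.loc[idx, "membership_start_year"] = year
        meta.loc[idx, "first_reporting_year"] = year

    meta.loc[3:12, "has_reference_estimates"] = False  # 10 countries

    # 31 BCG-excluded countries: indices 13..43
    meta.loc[13:26, "bcg_in_schedule"] = False                 # 14
    meta.loc[27:28, "bcg_target_is_full_birth_cohort"] = False  # 2
    meta.loc[29:29, "bcg_target_age_under_one"] = False         # 1 (age > 1 year)
    meta.loc[30:43, "ever_reported_bcg_target"] = False         # 14

    # 10 DTP3-excluded countries, a subset of the BCG-excluded set
    meta.loc[13:21, "ever_reported_dtp3_target"] = False        # 9
    meta.loc[22:22, "dtp3_target_age_under_one"] = False        # 1

    # 17 per-year BCG schedule overrides split across two included countries
    meta.loc[44, "bcg_excluded_years"] = ";".join(str(y) for y in range(2000, 2009))  # 9
    meta.loc[45, "bcg_excluded_years"] = ";".join(str(y) for y in range(2009, 2017))  # 8
    return meta


def generate_study_like_inputs(
    seed: int, year_range: tuple[int, int] = (2000, 2016)
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """A clean reported/reference panel over the study-scale metadata.

    Demographics are drawn as in :func:`generate_panel`; no anomalies are
    planted.  Countries that never reported a vaccine's target population
    have that target blanked (doses kept), consistent with their metadata.
    Returns (reports, reference, meta).
    """
    meta = make_study_metadata(year_range)
    config = GeneratorConfig(
        n_countries=len(meta),
        year_range=year_range,
        anomaly_rates={k: 0.0 for k in ANOMALY_KINDS},
        seed=seed,
    )
    rng = np.random.default_rng(config.seed)
    codes = list(meta["country_code"])
    panel = _build_clean_panel(config, rng, codes)
    reports, reference = _panel_to_frames(panel)

    never_bcg = set(meta.loc[~meta["ever_reported_bcg_target"], "country_code"])
    never_dtp3 = set(meta.loc[~meta["ever_reported_dtp3_target"], "country_code"])
    mask_bcg = (reports["vaccine"] == "BCG") & reports["country_code"].isin(never_bcg)
    mask_dtp3 = (reports["vaccine"].isin(["DTP1", "DTP3"])
                 & reports["country_code"].isin(never_dtp3))
    reports.loc[mask_bcg | mask_dtp3, "target_population"] = pd.NA
    return reports, reference, meta


def study_decisions(meta: pd.DataFrame,
                    year_range: tuple[int, int] = (2000, 2016)) -> pd.DataFrame:
    """Concatenated BCG + DTP3 eligibility ledger over the metadata's grid."""
    grid = build_event_grid(meta, year_range)
    bcg, _ = apply_eligibility(grid, meta, "BCG")
    dtp3, _ = apply_eligibility(grid, meta, "DTP3")
    return pd.concat([bcg, dtp3], ignore_index=True)


def plant_missing_targets(
    reports: pd.DataFrame,
    decisions: pd.DataFrame,
    vaccine: str,
    n: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank the target population of ``n`` randomly chosen included events.

    Only events that are included for ``vaccine`` and currently carry a
    target are candidates.  Returns (modified reports, chosen cells).
    """
    included = decisions[(decisions["vaccine"] == vaccine) & decisions["included"]]
    cells = set(zip(included["country_code"], included["year"]))
    sub = reports[reports["vaccine"] == vaccine]
    candidates = sub[
        sub["target_population"].notna()
        & np.array([c in cells for c in zip(sub["country_code"], sub["year"])], dtype=bool)
    ]
    if n > len(candidates):
        raise ValueError(f"cannot plant {n} missing targets in {len(candidates)} candidates")
    chosen = candidates.iloc[np.sort(rng.choice(len(candidates), size=n, replace=False))]
    out = reports.copy()
    out.loc[chosen.index, "target_population"] = pd.NA
    return out, chosen[["country_code", "year"]].reset_index(drop=True)


def plant_reference_divergence(
    reports: pd.DataFrame,
    reference: pd.DataFrame,
    decisions: pd.DataFrame,
    vaccine: str,
    n_higher: int,
    n_lower: int,
    rng: np.random.Generator,
    magnitude: tuple[float, float] = (15.0, 60.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale targets of chosen included events away from their reference value.

    ``n_higher`` events are pushed above the reference, ``n_lower`` below, by
    percentages drawn from ``magnitude``; doses are co-scaled so coverage is
    unchanged.  Returns (modified reports, chosen cells with signed percent).
    """
    ref_col = "live_births" if vaccine == "BCG" else "surviving_infants"
    included = decisions[(decisions["vaccine"] == vaccine) & decisions["included"]]
    cells = set(zip(included["country_code"], included["year"]))
    sub = reports[reports["vaccine"] == vaccine]
    candidates = sub[
        sub["target_population"].notna()
        & np.array([c in cells for c in zip(sub["country_code"], sub["year"])], dtype=bool)
    ]
    total = n_higher + n_lower
    if total > len(candidates):
        raise ValueError(f"cannot plant {total} divergences in {len(candidates)} candidates")
    chosen = candidates.iloc[np.sort(rng.choice(len(candidates), size=total, replace=False))]
    signs = np.concatenate([np.ones(n_higher), -np.ones(n_lower)])
    rng.shuffle(signs)
    pcts = rng.uniform(magnitude[0], magnitude[1], size=total) * signs

    out = reports.copy()
    ref = reference.set_index(["country_code", "year"])[ref_col]
    planted = []
    for (idx, row), pct in zip(chosen.iterrows(), pcts):
        ref_val = ref.loc[(row["country_code"], row["year"])]
        new_target = max(1, round(ref_val * (1.0 + pct / 100.0)))
        old_target = row["target_population"]
        out.loc[idx, "target_population"] = new_target
        if pd.notna(row["doses_administered"]) and old_target > 0:
            out.loc[idx, "doses_administered"] = round(
                row["doses_administered"] * new_target / old_target
            )
        planted.append({
            "country_code": row["country_code"],
            "year": row["year"],
            "planted_pct": 100.0 * (new_target - ref_val) / ref_val,
        })
    return out, pd.DataFrame(planted)
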