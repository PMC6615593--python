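"""Shared fixtures: tiny hand-written panels and random small-panel builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from denomqa.ingest import META_OPTIONAL_COLUMNS, REPORTED_COLUMNS


def make_meta(rows: list[dict]) -> pd.DataFrame:
    """Country metadata from partial dicts, defaulting to full eligibility."""
    defaults = {
        "region": "AFR",
        "membership_start_year": 2000,
        "first_reporting_year": 2000,
        "has_reference_estimates": True,
        "bcg_in_schedule": True,
        "bcg_target_is_full_birth_cohort": True,
        "bcg_target_age_under_one": True,
        "dtp3_target_age_under_one": True,
        "ever_reported_bcg_target": True,
        "ever_reported_dtp3_target": True,
    }
    out = pd.DataFrame([{**defaults, **row} for row in rows])
    for col in META_OPTIONAL_COLUMNS:
        if col not in out.columns:
            out[col] = ""
        out[col] = out[col].fillna("")
    return out


def make_reports(rows: list[tuple]) -> pd.DataFrame:
    """Reported panel from (country, year, vaccine, doses, target) tuples."""
    df = pd.DataFrame(rows, columns=REPORTED_COLUMNS)
    for col in ("doses_administered", "target_population"):
        df[col] = pd.array(df[col], dtype="Int64")
    return df


def make_reference(rows: list[tuple]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["country_code", "year", "live_births", "surviving_infants"])


def random_small_panel(rng: np.random.Generator, max_countries: int = 5, max_years: int = 5):
    """A random, messy panel of <= max_countries x max_years for oracle checks.

    Produces missing targets and doses, coverage above 100%, SI above LB,
    DTP1/DTP3 mismatches, sharp fluctuations, reference divergence, and
    random eligibility exclusions.
    """
    n = int(rng.integers(1, max_countries + 1))
    span = int(rng.integers(1, max_years + 1))
    year0 = 2000
    countries = [f"C{i:02d}" for i in range(n)]

    meta_rows = []
    for c in countries:
        meta_rows.append({
            "country_code": c,
            "first_reporting_year": int(year0 + rng.integers(0, max(1, span // 2))),
            "has_reference_estimates": bool(rng.random() > 0.1),
            "bcg_in_schedule": bool(rng.random() > 0.1),
            "ever_reported_dtp3_target": bool(rng.random() > 0.1),
        })
    meta = make_meta(meta_rows)

    rep_rows, ref_rows = [], []
    for c in countries:
        base = float(rng.uniform(1000, 5000))
        for y in range(year0, year0 + span):
            ref_lb = base * float(rng.uniform(0.9, 1.15))
            ref_si = ref_lb * float(rng.uniform(0.9, 1.0))
            ref_rows.append((c, y, ref_lb, ref_si))
            lb = round(ref_lb * rng.uniform(0.75, 1.3))
            si = round(ref_si * rng.uniform(0.75, 1.35))  # can exceed reported LB
            dtp1 = si if rng.random() < 0.6 else si + int(rng.integers(1, 50))
            doses_b = round(lb * rng.uniform(0.6, 1.2))
            doses_d = round(si * rng.uniform(0.6, 1.2))
            lb_v = lb if rng.random() > 0.2 else None
            si_v = si if rng.random() > 0.2 else None
            db_v = doses_b if rng.random() > 0.15 else None
            dd_v = doses_d if rng.random() > 0.15 else None
            d1_v = dtp1 if rng.random() > 0.2 else None
            rep_rows.append((c, y, "BCG", db_v, lb_v))
            rep_rows.append((c, y, "DTP3", dd_v, si_v))
            rep_rows.append((c, y, "DTP1", round(dtp1 * 0.9) if d1_v else None, d1_v))
    reports = make_reports(rep_rows)
    reference = make_reference(ref_rows)
    return reports, reference, meta, (year0, year0 + span - 1)


@pytest.fixture
def small_clean_panel():
    """3 countries x 3 years, reported equal to reference, flat 95% coverage."""
    countries = ["AAA", "BBB", "CCC"]
    rep_rows, ref_rows = [], []
    for c in countries:
        for y in (2000, 2001, 2002):
            lb, si = 1000, 950
            ref_rows.append((c, y, float(lb), float(si)))
            rep_rows.append((c, y, "BCG", 950, lb))
            rep_rows.append((c, y, "DTP3", 902, si))
            rep_rows.append((c, y, "DTP1", 902, si))
    meta = make_meta([{"country_code": c} for c in countries])
    return make_reports(rep_rows), make_reference(ref_rows), meta, (2000, 2002)
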