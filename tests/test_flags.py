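"""Flag engine over small panels: rule-by-rule behaviour and oracle parity."""

import numpy as np
import pandas as pd
import pytest

from denomqa import Thresholds, build_event_grid, apply_eligibility, evaluate_flags
from denomqa.flags import FLAG_IDS, compute_derived_statistics
from conftest import make_meta, make_reports, make_reference, random_small_panel
from _oracle import brute_force_flags


def _decisions(meta, year_range):
    grid = build_event_grid(meta, year_range)
    bcg, _ = apply_eligibility(grid, meta, "BCG")
    dtp3, _ = apply_eligibility(grid, meta, "DTP3")
    return pd.concat([bcg, dtp3], ignore_index=True)


def _flag(flags, country, year, flag_id):
    row = flags[(flags["country_code"] == country) & (flags["year"] == year)
                & (flags["flag_id"] == flag_id)]
    assert len(row) == 1
    return row.iloc[0]


class TestHandEvaluatedCountryYear:
    """SI 1100 > LB 1000 with reference SI 980 fires F6 and F8 but not F9."""

    @pytest.fixture
    def flags(self):
        meta = make_meta([{"country_code": "XXA"}])
        reports = make_reports([
            ("XXA", 2000, "BCG", 900, 1000),
            ("XXA", 2000, "DTP3", 990, 1100),
            ("XXA", 2000, "DTP1", 990, 1100),
        ])
        reference = make_reference([("XXA", 2000, 1000.0, 980.0)])
        return evaluate_flags(reports, reference, _decisions(meta, (2000, 2000)))

    def test_negative_imr_fires(self, flags):
        rec = _flag(flags, "XXA", 2000, "F6_NEG_IMR")
        assert rec["fired"] and rec["statistic_value"] == pytest.approx(-100.0)

    def test_si_reference_divergence_fires(self, flags):
        rec = _flag(flags, "XXA", 2000, "F8_SI_REF_DIFF_GT10")
        assert rec["fired"]
        assert rec["statistic_value"] == pytest.approx(100 * (1100 - 980) / 980)

    def test_dtp_targets_agree_so_no_mismatch(self, flags):
        rec = _flag(flags, "XXA", 2000, "F9_DTP3_NE_DTP1")
        assert rec["evaluable"] and not rec["fired"]

    def test_lb_matches_reference(self, flags):
        assert not _flag(flags, "XXA", 2000, "F7_LB_REF_DIFF_GT10")["fired"]


def test_clean_panel_fires_nothing(small_clean_panel):
    reports, reference, meta, year_range = small_clean_panel
    flags = evaluate_flags(reports, reference, _decisions(meta, year_range))
    assert flags["fired"].sum() == 0
    # every country-year carries one record per flag
    assert len(flags) == 9 * 9
    assert set(flags["flag_id"]) == set(FLAG_IDS)


class TestBoundaries:
    def test_exact_ten_percent_jump_does_not_fire(self):
        meta = make_meta([{"country_code": "BND"}])
        reports = make_reports([
            ("BND", 2000, "BCG", 900, 1000), ("BND", 2001, "BCG", 990, 1100),
            ("BND", 2000, "DTP3", 900, 1000), ("BND", 2001, "DTP3", 990, 1100),
        ])
        reference = make_reference([("BND", 2000, 1000.0, 1000.0),
                                    ("BND", 2001, 1100.0, 1100.0)])
        flags = evaluate_flags(reports, reference, _decisions(meta, (2000, 2001)))
        rec = _flag(flags, "BND", 2001, "F3_YOY_DENOM_GT10")
        assert rec["evaluable"] and not rec["fired"]
        assert rec["statistic_value"] == pytest.approx(10.0)

    def test_exact_hundred_coverage_does_not_fire(self):
        meta = make_meta([{"country_code": "BND"}])
        reports = make_reports([("BND", 2000, "BCG", 1000, 1000),
                                ("BND", 2000, "DTP3", 1000, 1000),
                                ("BND", 2000, "DTP1", 1000, 1000)])
        reference = make_reference([("BND", 2000, 1000.0, 1000.0)])
        flags = evaluate_flags(reports, reference, _decisions(meta, (2000, 2000)))
        assert not _flag(flags, "BND", 2000, "F5_COV_GT100")["fired"]


class TestMissingYearGaps:
    """Deleting year t kills both adjacent pairs and never bridges the gap."""

    def test_gap_makes_neighbouring_pairs_non_evaluable(self):
        meta = make_meta([{"country_code": "GAP"}])
        rows = []
        for y, target in ((2000, 1000), (2001, None), (2002, 2000)):
            rows.append(("GAP", y, "BCG", 900, target))
            rows.append(("GAP", y, "DTP3", 900, target))
        reports = make_reports(rows)
        reference = make_reference([("GAP", y, 1500.0, 1480.0) for y in (2000, 2001, 2002)])
        stats = compute_derived_statistics(reports, reference, _decisions(meta, (2000, 2002)))
        yoy = stats.set_index("year")["yoy_diff_lb"]
        assert np.isnan(yoy[2001]) and np.isnan(yoy[2002])
        flags = evaluate_flags(reports, reference, _decisions(meta, (2000, 2002)))
        # despite the 2x change 2000 -> 2002, no pair bridges the gap
        for y in (2001, 2002):
            assert not _flag(flags, "GAP", y, "F3_YOY_DENOM_GT10")["evaluable"]

    def test_ineligible_prior_year_blocks_pair(self):
        meta = make_meta([{"country_code": "LAT", "first_reporting_year": 2001,
                           "membership_start_year": 2001}])
        reports = make_reports([("LAT", 2001, "BCG", 900, 1000),
                                ("LAT", 2002, "BCG", 900, 3000)])
        reference = make_reference([("LAT", y, 1000.0, 990.0) for y in (2000, 2001, 2002)])
        flags = evaluate_flags(reports, reference, _decisions(meta, (2000, 2002)))
        assert not _flag(flags, "LAT", 2001, "F3_YOY_DENOM_GT10")["evaluable"]
        assert _flag(flags, "LAT", 2002, "F3_YOY_DENOM_GT10")["fired"]


class TestPartialEligibility:
    def test_bcg_excluded_country_gets_dtp3_flags_only(self):
        meta = make_meta([{"country_code": "NOB", "bcg_in_schedule": False}])
        reports = make_reports([("NOB", 2000, "DTP3", 950, 1000),
                                ("NOB", 2000, "DTP1", 950, 1000),
                                ("NOB", 2000, "BCG", 2000, 1000)])  # ignored: excluded
        reference = make_reference([("NOB", 2000, 1010.0, 1000.0)])
        flags = evaluate_flags(reports, reference, _decisions(meta, (2000, 2000)))
        assert not _flag(flags, "NOB", 2000, "F1_LB_MISSING")["evaluable"]
        assert not _flag(flags, "NOB", 2000, "F5_COV_GT100")["fired"]  # BCG 200% ignored
        assert not _flag(flags, "NOB", 2000, "F6_NEG_IMR")["evaluable"]
        assert _flag(flags, "NOB", 2000, "F2_SI_MISSING")["evaluable"]

    def test_missing_dtp1_target_makes_mismatch_non_evaluable(self):
        meta = make_meta([{"country_code": "ND1"}])
        reports = make_reports([("ND1", 2000, "BCG", 900, 1000),
                                ("ND1", 2000, "DTP3", 900, 1000)])
        reference = make_reference([("ND1", 2000, 1000.0, 1000.0)])
        flags = evaluate_flags(reports, reference, _decisions(meta, (2000, 2000)))
        rec = _flag(flags, "ND1", 2000, "F9_DTP3_NE_DTP1")
        assert not rec["evaluable"] and not rec["fired"]


class TestOracleEquivalence:
    """The vectorised engine matches a brute-force rule checker on random panels."""

    @pytest.mark.parametrize("seed", range(25))
    def test_random_small_panels(self, seed):
        rng = np.random.default_rng(seed)
        reports, reference, meta, year_range = random_small_panel(rng)
        decisions = _decisions(meta, year_range)
        flags = evaluate_flags(reports, reference, decisions)
        expected = brute_force_flags(
            reports.to_dict("records"), reference.to_dict("records"),
            decisions.to_dict("records"))
        got = {
            (r["country_code"], r["year"]): {}
            for _, r in flags.iterrows()
        }
        for _, r in flags.iterrows():
            got[(r["country_code"], r["year"])][r["flag_id"]] = (
                bool(r["evaluable"]), bool(r["fired"]))
        assert set(got) == set(expected)
        for cell in expected:
            assert got[cell] == expected[cell], f"mismatch at {cell}"
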