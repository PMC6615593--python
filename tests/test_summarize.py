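"""Summary surfaces: tallies, distributions, direction counts, regional sums."""

import numpy as np
import pandas as pd
import pytest

from denomqa import (
    GeneratorConfig,
    evaluate_flags,
    direction_analysis,
    flag_count_distribution,
    generate_panel,
    regional_aggregate,
    sum_flags_per_country_year,
    tabulate_indicator_summary,
)
from denomqa.flags import FLAG_IDS, compute_derived_statistics, evaluate_indicators
from denomqa.summarize import round_half_away
from denomqa.synthetic import study_decisions
from conftest import make_meta, make_reports, make_reference


def _flag_frame(rows):
    """rows: (country, year, flag_id, evaluable, fired, value, threshold)."""
    return pd.DataFrame(rows, columns=[
        "country_code", "year", "flag_id", "evaluable", "fired",
        "statistic_value", "threshold"])


@pytest.fixture(scope="module")
def anomalous_run():
    config = GeneratorConfig(n_countries=30, seed=42)
    reports, reference, meta, truth = generate_panel(config)
    decisions = study_decisions(meta)
    flags = evaluate_flags(reports, reference, decisions)
    stats = compute_derived_statistics(reports, reference, decisions)
    indicators = evaluate_indicators(stats)
    return reports, reference, meta, decisions, flags, indicators


class TestFlagSums:
    def test_fired_flags_are_counted_and_non_evaluable_contribute_zero(self):
        rows = [("AAA", 2000, "F6_NEG_IMR", True, True, -5.0, 0.0),
                ("AAA", 2000, "F8_SI_REF_DIFF_GT10", True, True, 12.2, 10.0),
                ("AAA", 2000, "F3_YOY_DENOM_GT10", False, False, np.nan, 10.0),
                ("BBB", 2000, "F6_NEG_IMR", True, False, 5.0, 0.0)]
        counts = sum_flags_per_country_year(_flag_frame(rows))
        assert counts.set_index("country_code")["n_flags"].to_dict() == {"AAA": 2, "BBB": 0}

    def test_all_nine_fired_is_the_upper_bound(self):
        rows = [("AAA", 2000, f, True, True, 1.0, 0.0) for f in FLAG_IDS]
        counts = sum_flags_per_country_year(_flag_frame(rows))
        assert counts["n_flags"].tolist() == [9]


class TestIndicatorSummary:
    def test_percentages_round_half_away_from_zero(self):
        # 194/2565 = 7.56% -> 8; 274/2939 = 9.32% -> 9
        assert round_half_away(100 * 194 / 2565) == 8
        assert round_half_away(100 * 274 / 2939) == 9
        assert round_half_away(7.5) == 8
        assert round_half_away(-7.5) == -8

    def test_zero_fired_gives_zero_country_tallies(self):
        ind = pd.DataFrame({
            "country_code": ["AAA"] * 3, "year": [2000, 2001, 2002],
            "indicator": "neg_imr", "threshold_variant": 0.0,
            "evaluable": True, "fired": False, "value": 5.0})
        table = tabulate_indicator_summary(ind)
        row = table.iloc[0]
        assert row["events_evaluable"] == 3 and row["events_fired"] == 0
        assert row["countries_fired_any_year"] == 0
        assert row["countries_fired_ge5_years"] == 0

    def test_nesting_monotonicity_on_generated_panel(self, anomalous_run):
        *_, indicators = anomalous_run
        table = tabulate_indicator_summary(indicators)
        assert (table["events_fired"] <= table["events_evaluable"]).all()
        assert (table["countries_fired_ge10_years"]
                <= table["countries_fired_ge5_years"]).all()
        assert (table["countries_fired_ge5_years"]
                <= table["countries_fired_any_year"]).all()
        assert (table["countries_fired_any_year"] <= table["countries_total"]).all()


class TestDistribution:
    def test_country_with_six_flags_lands_in_top_bin(self):
        per_cy = pd.DataFrame({"country_code": ["AAA"], "year": [2001], "n_flags": [6]})
        dist = flag_count_distribution(per_cy, [2001])
        assert dist.set_index("bin")["n_countries"]["5+"] == 1

    def test_three_country_toy_histogram(self):
        per_cy = pd.DataFrame({"country_code": ["A", "B", "C"], "year": 2000,
                               "n_flags": [0, 0, 4]})
        dist = flag_count_distribution(per_cy, [2000]).set_index("bin")["n_countries"]
        assert dist.to_dict() == {"0": 2, "1": 0, "2": 0, "3": 0, "4": 1, "5+": 0}

    def test_requested_year_without_countries_gives_all_zero_bins(self):
        per_cy = pd.DataFrame({"country_code": ["A", "A"], "year": [2000, 2002],
                               "n_flags": [1, 2]})
        dist = flag_count_distribution(per_cy, [2001])
        assert (dist["n_countries"] == 0).all()

    def test_year_outside_range_rejected(self):
        per_cy = pd.DataFrame({"country_code": ["A"], "year": [2000], "n_flags": [0]})
        with pytest.raises(ValueError, match="2050"):
            flag_count_distribution(per_cy, [2050])

    def test_histogram_conserves_country_counts(self, anomalous_run):
        *_, flags, _ = anomalous_run
        per_cy = sum_flags_per_country_year(flags)
        years = sorted(per_cy["year"].unique())
        dist = flag_count_distribution(per_cy, years)
        for y in years:
            n_counted = (per_cy["year"] == y).sum()
            assert dist.loc[dist["year"] == y, "n_countries"].sum() == n_counted


class TestDirection:
    def test_signed_statistics_split_into_higher_and_lower(self):
        rows = [("A", 2000, "F7_LB_REF_DIFF_GT10", True, True, 12.0, 10.0),
                ("B", 2000, "F7_LB_REF_DIFF_GT10", True, True, -15.0, 10.0),
                ("C", 2000, "F7_LB_REF_DIFF_GT10", True, True, -11.0, 10.0)]
        out = direction_analysis(_flag_frame(rows)).set_index("flag_id")
        row = out.loc["F7_LB_REF_DIFF_GT10"]
        assert (row["higher_than_reference"], row["lower_than_reference"]) == (1, 2)

    def test_no_fired_events_gives_zeroes(self):
        out = direction_analysis(_flag_frame([]))
        assert (out[["higher_than_reference", "lower_than_reference"]] == 0).all().all()

    def test_higher_plus_lower_equals_fired(self, anomalous_run):
        *_, flags, _ = anomalous_run
        out = direction_analysis(flags)
        assert (out["higher_than_reference"] + out["lower_than_reference"]
                == out["events_fired"]).all()


class TestRegionalAggregate:
    def _identity_panel(self):
        meta = make_meta([{"country_code": "AAA", "region": "AFR"},
                          {"country_code": "BBB", "region": "AFR"}])
        rep_rows, ref_rows = [], []
        for c, base in (("AAA", 1000), ("BBB", 2000)):
            for y in (2000, 2001):
                ref_rows.append((c, y, float(base), float(base) * 0.95))
                rep_rows.append((c, y, "BCG", base, base))
                rep_rows.append((c, y, "DTP3", base, round(base * 0.95)))
                rep_rows.append((c, y, "DTP1", base, round(base * 0.95)))
        return make_reports(rep_rows), make_reference(ref_rows), meta

    def test_identity_when_reported_equals_reference(self):
        reports, reference, meta = self._identity_panel()
        decisions = study_decisions(meta, (2000, 2001))
        out = regional_aggregate(reports, reference, decisions, meta)
        assert np.allclose(out["reported_lb"], out["reference_lb"])
        assert np.allclose(out["reported_si"], out["reference_si"])
        assert set(out["region"]) == {"AFR"}

    def test_planted_excess_appears_exactly_in_reported_sum(self):
        reports, reference, meta = self._identity_panel()
        decisions = study_decisions(meta, (2000, 2001))
        # one country reports 10.16x its reference SI in 2001
        mask = ((reports["country_code"] == "AAA") & (reports["year"] == 2001)
                & (reports["vaccine"] == "DTP3"))
        ref_si = 950.0
        reports.loc[mask, "target_population"] = round(ref_si * 10.16)
        out = regional_aggregate(reports, reference, decisions, meta)
        row = out[out["year"] == 2001].iloc[0]
        excess = round(ref_si * 10.16) - ref_si
        assert row["reported_si"] - row["reference_si"] == pytest.approx(excess)

    def test_missing_report_drops_from_reported_sum_only(self):
        reports, reference, meta = self._identity_panel()
        decisions = study_decisions(meta, (2000, 2001))
        mask = ((reports["country_code"] == "BBB") & (reports["year"] == 2001)
                & (reports["vaccine"] == "BCG"))
        reports.loc[mask, "target_population"] = pd.NA
        out = regional_aggregate(reports, reference, decisions, meta)
        row = out[out["year"] == 2001].iloc[0]
        assert row["reported_lb"] == 1000.0       # BBB's 2000 dropped out
        assert row["reference_lb"] == 3000.0      # reference side stays put

    def test_permutation_invariance_in_country_order(self, anomalous_run):
        reports, reference, meta, decisions, *_ = anomalous_run
        out1 = regional_aggregate(reports, reference, decisions, meta)
        shuffled = meta.sample(frac=1.0, random_state=0)
        out2 = regional_aggregate(
            reports.sample(frac=1.0, random_state=1), reference, decisions, shuffled)
        pd.testing.assert_frame_equal(out1, out2)

    def test_unknown_region_country_rejected(self):
        reports, reference, meta = self._identity_panel()
        decisions = study_decisions(meta, (2000, 2001))
        with pytest.raises(ValueError, match="metadata"):
            regional_aggregate(reports, reference, decisions,
                               meta[meta["country_code"] != "AAA"])
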