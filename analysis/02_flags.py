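"""Apply the eligibility cascade and evaluate the nine flags on the panel.

Reads results/panel/, writes the eligibility ledger, derived statistics
(coverage, year-to-year differences, reference differences, implied IMR),
flag records and indicator records under results/flags/.
"""

from pathlib import Path

import pandas as pd

from denomqa import apply_eligibility, build_event_grid
from denomqa.eligibility import write_decisions
from denomqa.flags import (
    Thresholds,
    compute_derived_statistics,
    evaluate_flags_from_stats,
    evaluate_indicators,
    write_flags,
)
from denomqa.ingest import read_country_meta, read_reference_panel, read_reported_panel

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    meta = read_country_meta(ROOT / "panel" / "country_meta.csv")
    reports = read_reported_panel(ROOT / "panel" / "reported.csv")
    grid = build_event_grid(meta, (2000, 2016))
    reference = read_reference_panel(ROOT / "panel" / "reference.csv", expected_grid=grid)

    pieces = []
    for vaccine in ("BCG", "DTP3"):
        decisions, summary = apply_eligibility(grid, meta, vaccine)
        pieces.append(decisions)
        print(f"{vaccine}: {summary.included_events}/{summary.grid_total} events included "
              f"across {summary.included_countries} countries "
              f"(exclusions: {summary.excluded_by_reason or 'none'})")
    decisions = pd.concat(pieces, ignore_index=True)

    thresholds = Thresholds()
    stats = compute_derived_statistics(reports, reference, decisions)
    flags = evaluate_flags_from_stats(stats, thresholds)
    indicators = evaluate_indicators(stats, thresholds)

    out = ROOT / "flags"
    out.mkdir(parents=True, exist_ok=True)
    write_decisions(decisions, out / "decisions.csv")
    stats.to_csv(out / "derived_statistics.csv", index=False)
    write_flags(flags, out / "flags.csv")
    indicators.to_csv(out / "indicators.csv", index=False)

    fired = flags[flags["fired"]].groupby("flag_id").size()
    evaluable = flags[flags["evaluable"]].groupby("flag_id").size()
    print("\nFlag firings (fired / evaluable events):")
    for flag_id in evaluable.index:
        print(f"  {flag_id:<22s} {fired.get(flag_id, 0):>4d} / {evaluable[flag_id]}")
    print(f"Wrote flag tables to {out}")


if __name__ == "__main__":
    main()
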