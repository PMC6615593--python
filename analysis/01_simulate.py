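"""Generate the working panel: 194 synthetic countries, 2000-2016.

Produces a reported panel (BCG/DTP1/DTP3 doses and target populations), a
reference demographic panel, country metadata and a truth ledger of planted
anomalies, all under results/panel/.  The default configuration plants
missingness, denominator jumps, coverage above 100%, negative implied IMR,
reference divergence and DTP1/DTP3 mismatches at rates of a few percent per
country-year each, echoing how common these inconsistencies are in real
national reporting.
"""

from pathlib import Path

from denomqa import GeneratorConfig, generate_panel
from denomqa.ingest import write_country_meta, write_reference_panel, write_reported_panel

SEED = 20160101
OUT = Path(__file__).resolve().parent.parent / "results" / "panel"


def main() -> None:
    config = GeneratorConfig(seed=SEED)
    reports, reference, meta, truth = generate_panel(config)
    OUT.mkdir(parents=True, exist_ok=True)
    write_reported_panel(reports, OUT / "reported.csv")
    write_reference_panel(reference, OUT / "reference.csv")
    write_country_meta(meta, OUT / "country_meta.csv")
    truth.to_csv(OUT / "truth_ledger.csv", index=False)

    by_kind = truth["anomaly_kind"].value_counts()
    n_cells = config.n_countries * (config.year_range[1] - config.year_range[0] + 1)
    print(f"Simulated {config.n_countries} countries x 17 years "
          f"({len(reports)} reporting events) with seed {SEED}.")
    print(f"Planted {len(truth)} anomalies over {n_cells} country-years "
          f"({100 * len(truth) / n_cells:.1f}% of cells):")
    for kind, n in by_kind.items():
        print(f"  {kind:<22s} {n}")
    print(f"Wrote panel and truth ledger to {OUT}")


if __name__ == "__main__":
    main()
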