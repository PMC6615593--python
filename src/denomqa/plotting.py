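"""Figure rendering for the summary surfaces (optional, matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from denomqa.flags import coverage_error_from_denominator_error
from denomqa.summarize import DISTRIBUTION_BINS


def plot_coverage_error_curve(path, denominator_errors=(-0.10, 0.10)) -> None:
    """Coverage error in percentage points as true coverage rises.

    Illustrates why denominator quality matters more in high-coverage
    programs: a fixed relative error in the target population produces a
    coverage error that grows with coverage itself.
    """
    cov = np.linspace(0, 100, 201)
    fig, ax = plt.subplots(figsize=(6, 4))
    for err in denominator_errors:
        ax.plot(cov, coverage_error_from_denominator_error(cov, err),
                label=f"denominator error {err:+.0%}")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("true coverage (%)")
    ax.set_ylabel("coverage error (percentage points)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_flag_count_distribution(dist: pd.DataFrame, path) -> None:
    """Grouped bars: countries by number of flags fired, per selected year."""
    years = list(dict.fromkeys(dist["year"]))
    x = np.arange(len(DISTRIBUTION_BINS))
    width = 0.8 / max(len(years), 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    for k, year in enumerate(years):
        sub = dist[dist["year"] == year].set_index("bin")["n_countries"]
        ax.bar(x + k * width, [sub.get(b, 0) for b in DISTRIBUTION_BINS],
               width=width, label=str(year))
    ax.set_xticks(x + width * (len(years) - 1) / 2)
    ax.set_xticklabels(DISTRIBUTION_BINS)
    ax.set_xlabel("number of flags fired")
    ax.set_ylabel("countries")
    ax.legend(title="year")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_regional_series(regional: pd.DataFrame, path) -> None:
    """Reported vs reference denominator sums per region over time."""
    regions = sorted(regional["region"].unique())
    fig, axes = plt.subplots(2, 3, figsize=(12, 6), sharex=True)
    for ax, region in zip(axes.flat, regions):
        sub = regional[regional["region"] == region].sort_values("year")
        ax.plot(sub["year"], sub["reported_lb"] / 1e6, label="reported LB")
        ax.plot(sub["year"], sub["reference_lb"] / 1e6, "--", label="reference LB")
        ax.plot(sub["year"], sub["reported_si"] / 1e6, label="reported SI")
        ax.plot(sub["year"], sub["reference_si"] / 1e6, "--", label="reference SI")
        ax.set_title(region)
        ax.set_ylabel("millions")
    axes.flat[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
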