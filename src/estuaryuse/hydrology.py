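"""Wet/dry hydrological-year classification from seasonal river discharge.

A study year is classified against a multi-year baseline using the mean daily
discharge over the beluga estuarine season, 14 July–31 August (49 days,
inclusive). The baseline is the mean of yearly seasonal means over the
reference period; a year is "wet" when its percent deviation from that
baseline is positive, otherwise "dry" (years at or near the average count as
dry). The wet threshold is exposed for sensitivity analysis but defaults
to zero deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "SEASON_START",
    "SEASON_END",
    "YearClassification",
    "seasonal_mean",
    "percent_deviation",
    "classify_wet_dry",
    "classify_series",
]

SEASON_START = "07-14"
SEASON_END = "08-31"
_WINDOW_DAYS = 49


@dataclass(frozen=True)
class YearClassification:
    year: int
    seasonal_mean_m3s: float
    baseline_mean_m3s: float
    deviation_pct: float  # unrounded
    deviation_pct_rounded: int
    label: str  # "wet" or "dry"


def seasonal_mean(series: pd.DataFrame, year: int, max_missing_frac: float = 0.10) -> float:
    """Mean daily discharge (m³/s) over 14 Jul–31 Aug of ``year``.

    Tolerates up to ``max_missing_frac`` of the 49-day window missing (with a
    warning); beyond that the year is rejected.
    """
    dates = pd.to_datetime(series["date"])
    mask = (dates >= f"{year}-{SEASON_START}") & (dates <= f"{year}-{SEASON_END}")
    window = series.loc[mask, "discharge_m3s"]
    n = len(window)
    missing = _WINDOW_DAYS - n
    if missing > max_missing_frac * _WINDOW_DAYS:
        raise ValueError(
            f"{year}: {missing} of {_WINDOW_DAYS} window days missing "
            f"(> {max_missing_frac:.0%} allowed)"
        )
    if missing > 0:
        warnings.warn(f"{year}: {missing} of {_WINDOW_DAYS} window days missing")
    if (window <= 0).any():
        raise ValueError(f"{year}: non-positive discharge values in window")
    return float(window.mean())


def percent_deviation(year_mean: float, baseline_mean: float) -> tuple[float, int]:
    """Percent deviation of a year's seasonal mean from the baseline.

    Returns ``(unrounded, integer-rounded)``; e.g. (5176, 3331) → +55%.
    """
    if baseline_mean <= 0:
        raise ValueError("baseline_mean must be positive")
    dev = 100.0 * (year_mean - baseline_mean) / baseline_mean
    return dev, int(round(dev))


def classify_wet_dry(
    year_means: dict,
    baseline_mean: float,
    wet_threshold_pct: float = 0.0,
) -> list[YearClassification]:
    """Classify each year wet/dry from its seasonal mean and the baseline.

    Wet iff deviation_pct > ``wet_threshold_pct`` (strict: a year exactly at
    the average is "dry").
    """
    out = []
    for year in sorted(year_means):
        dev, dev_r = percent_deviation(year_means[year], baseline_mean)
        out.append(
            YearClassification(
                year=int(year),
                seasonal_mean_m3s=float(year_means[year]),
                baseline_mean_m3s=float(baseline_mean),
                deviation_pct=dev,
                deviation_pct_rounded=dev_r,
                label="wet" if dev > wet_threshold_pct else "dry",
            )
        )
    return out


def classify_series(
    series: pd.DataFrame,
    study_years,
    baseline_years,
    wet_threshold_pct: float = 0.0,
) -> list[YearClassification]:
    """End-to-end classification from a daily discharge table.

    The baseline is the mean of the yearly seasonal means over
    ``baseline_years`` ("averaged by year", not a grand mean of days).
    """
    baseline_means = [seasonal_mean(series, y) for y in baseline_years]
    if not baseline_means:
        raise ValueError("baseline_years must not be empty")
    baseline = sum(baseline_means) / len(baseline_means)
    year_means = {y: seasonal_mean(series, y) for y in study_years}
    return classify_wet_dry(year_means, baseline, wet_threshold_pct)
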