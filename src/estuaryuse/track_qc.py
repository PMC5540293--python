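"""Argos track quality control.

Raw Argos data arrive as duplicate message solutions with heterogeneous
location quality. The analysis-grade track is obtained in three stages:

1. ``dedupe_best`` — keep the best location solution per duplicate group;
2. ``filter_quality`` — keep only "guaranteed" precision classes (3/2/1,
   roughly 250 m–1.5 km error);
3. ``filter_speed`` — drop fixes implying travel faster than a biological
   maximum (default 3.5 km/h) from the last retained fix.

Each stage is idempotent and never reorders fixes within a whale; counts are
non-increasing through the chain, which ``qc_report`` asserts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from ._geodesy import great_circle_km

logger = logging.getLogger(__name__)

__all__ = [
    "GUARANTEED_CLASSES",
    "CLASS_ORDER",
    "FilterReport",
    "dedupe_best",
    "filter_quality",
    "filter_speed",
    "qc_report",
    "run_qc",
]

#: Argos classes ordered best→worst; Z means no usable location quality.
CLASS_ORDER = ("3", "2", "1", "0", "A", "B", "Z")
GUARANTEED_CLASSES = frozenset({"3", "2", "1"})

_CLASS_RANK = {c: i for i, c in enumerate(CLASS_ORDER)}


@dataclass(frozen=True)
class FilterReport:
    """Record counts through the QC chain and the overall retention fraction."""

    n_input: int
    n_after_dedupe: int
    n_after_quality: int
    n_after_speed: int
    retention_fraction: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _class_rank(series: pd.Series) -> pd.Series:
    rank = series.astype(str).map(_CLASS_RANK)
    if rank.isna().any():
        bad = series[rank.isna()].iloc[0]
        raise ValueError(f"unknown Argos location class {bad!r}")
    return rank


def dedupe_best(fixes: pd.DataFrame) -> pd.DataFrame:
    """One fix per duplicate message group: best class wins, ties → earliest.

    Groups come from a ``duplicate_group`` column when present, otherwise
    fixes of the same whale with identical timestamps are treated as
    duplicates. Output is time-sorted within whale.
    """
    if len(fixes) == 0:
        return fixes.copy()
    df = fixes.copy()
    df["_rank"] = _class_rank(df["location_class"])
    group_key = (
        "duplicate_group"
        if "duplicate_group" in df.columns and df["duplicate_group"].notna().all()
        else "timestamp"
    )
    df["_order"] = np.arange(len(df))  # receipt order for tie-breaking
    df = df.sort_values(["whale_id", group_key, "_rank", "_order"], kind="stable")
    kept = df.groupby(["whale_id", group_key], sort=False).head(1)
    kept = kept.sort_values(["whale_id", "timestamp", "_order"], kind="stable")
    return kept.drop(columns=["_rank", "_order"]).reset_index(drop=True)


def filter_quality(fixes: pd.DataFrame, allowed_classes=GUARANTEED_CLASSES) -> pd.DataFrame:
    """Keep only fixes whose location class is in ``allowed_classes``.

    Raises on unknown class symbols, naming the offending record.
    """
    if len(fixes) == 0:
        return fixes.copy()
    cls = fixes["location_class"].astype(str)
    unknown = ~cls.isin(_CLASS_RANK)
    if unknown.any():
        row = fixes[unknown].iloc[0]
        raise ValueError(
            f"unknown Argos location class {row['location_class']!r} "
            f"for whale {row['whale_id']} at {row['timestamp']}"
        )
    allowed = {str(c) for c in allowed_classes}
    return fixes[cls.isin(allowed)].reset_index(drop=True)


def filter_speed(fixes: pd.DataFrame, vmax_km_h: float = 3.5) -> pd.DataFrame:
    """Forward sequential travel-rate filter, per whale.

    Walking each whale's time-sorted fixes, a fix is dropped when the
    great-circle speed from the last *retained* fix is ≥ ``vmax_km_h``.
    The first fix is always retained. A zero or negative time gap between
    distinct positions makes the implied speed infinite, so the later fix is
    dropped (and logged).
    """
    if vmax_km_h <= 0:
        raise ValueError("vmax_km_h must be positive")
    if len(fixes) == 0:
        return fixes.copy()
    keep_masks = []
    for wid, grp in fixes.groupby("whale_id", sort=False):
        ts = pd.to_datetime(grp["timestamp"]).to_numpy()
        if np.any(np.diff(ts) < np.timedelta64(0)):
            raise ValueError(f"fixes for whale {wid} are not time-sorted")
        lon = grp["lon"].to_numpy(float)
        lat = grp["lat"].to_numpy(float)
        keep = np.zeros(len(grp), dtype=bool)
        keep[0] = True
        last = 0
        for i in range(1, len(grp)):
            dt_h = (ts[i] - ts[last]) / np.timedelta64(1, "h")
            d_km = great_circle_km(lon[last], lat[last], lon[i], lat[i])
            if dt_h <= 0:
                if d_km == 0.0 and dt_h == 0.0:
                    # exact duplicate position+time: harmless, keep out
                    logger.info("whale %s: duplicate timestamp fix dropped", wid)
                else:
                    logger.warning(
                        "whale %s: non-positive time gap at %s; fix dropped", wid, ts[i]
                    )
                continue
            if d_km / dt_h < vmax_km_h:
                keep[i] = True
                last = i
        keep_masks.append(pd.Series(keep, index=grp.index))
    mask = pd.concat(keep_masks).reindex(fixes.index, fill_value=False)
    return fixes[mask].reset_index(drop=True)


def qc_report(n_input: int, n_after_dedupe: int, n_after_quality: int, n_after_speed: int) -> FilterReport:
    """Build a :class:`FilterReport`, asserting monotone counts."""
    counts = [n_input, n_after_dedupe, n_after_quality, n_after_speed]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if any(a < b for a, b in zip(counts, counts[1:])):
        raise ValueError(f"stage counts must be non-increasing, got {counts}")
    retention = n_after_speed / n_input if n_input else 0.0
    return FilterReport(*counts, retention_fraction=retention)


def run_qc(
    fixes: pd.DataFrame,
    allowed_classes=GUARANTEED_CLASSES,
    vmax_km_h: float = 3.5,
) -> tuple[pd.DataFrame, FilterReport]:
    """Full QC chain (dedupe → quality → speed) with its report."""
    deduped = dedupe_best(fixes)
    quality = filter_quality(deduped, allowed_classes)
    final = filter_speed(quality, vmax_km_h)
    report = qc_report(len(fixes), len(deduped), len(quality), len(final))
    return final, report
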