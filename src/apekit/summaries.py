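"""Daily validity rules, MET/APE histograms, and hour-by-hour profiles.

A monitored day is *valid* when the device was worn essentially the whole
day (default at least 1436 of 1440 min, configurable) and the upright
reference vector was set at least 10 times. A participant is included when
at least four valid days are available; per-bin daily means are taken over
valid days only.

MET histograms use nine bins of width 1.5 MET, from below 1.5 to 12 and
over. The bins roll up into intensity categories: below 1.5 MET is
stationary behavior, 1.5-3 light, 3-6 moderate, 6-9 vigorous, and 9 and
above very vigorous physical activity. Sleep-log intervals are excluded
from all behavior summaries (the device is moved to the wrist in bed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .posture import APE_BIN_EDGES, POSTURE_LABELS, ape_bin_labels, build_ape_histogram
from .types import SleepLog

#: Nine MET bins of width 1.5; first bin is everything below 1.5, last is >= 12.
MET_BIN_EDGES = np.array([0.0, 1.5, 3.0, 4.5, 6.0, 7.5, 9.0, 10.5, 12.0, np.inf])

MET_BIN_CATEGORIES = (
    "stationary",
    "light",
    "moderate",
    "moderate",
    "vigorous",
    "vigorous",
    "very_vigorous",
    "very_vigorous",
    "very_vigorous",
)


def met_bin_labels() -> list[str]:
    """Short labels for the nine MET bins."""

    def fmt(x: float) -> str:
        return str(x).replace(".", "p").removesuffix("p0")

    labels = [f"{fmt(lo)}_{fmt(hi)}" for lo, hi in zip(MET_BIN_EDGES[1:-2], MET_BIN_EDGES[2:-1])]
    return ["lt_1p5", *labels, "ge_12"]


def met_bin_columns() -> list[str]:
    return [f"met_min_{l}" for l in met_bin_labels()]


def ape_bin_columns() -> list[str]:
    return [f"ape_min_{l}" for l in ape_bin_labels()]


def awake_mask(epochs: pd.DataFrame, sleep_log: SleepLog | None) -> np.ndarray:
    """Epochs whose start time falls outside every in-bed interval."""
    if sleep_log is None:
        return np.ones(len(epochs), dtype=bool)
    return ~sleep_log.in_bed(epochs["start_time"])


def build_met_histogram(
    epochs: pd.DataFrame, sleep_log: SleepLog | None = None, epoch_s: float = 6.0
) -> pd.DataFrame:
    """Minutes per MET bin over worn, awake epochs with a defined MET."""
    met = epochs["met"].to_numpy(dtype=float)
    keep = epochs["wear"].to_numpy(dtype=bool) & awake_mask(epochs, sleep_log) & np.isfinite(met)
    edges = MET_BIN_EDGES.copy()
    edges[-1] = np.finfo(float).max
    counts, _ = np.histogram(met[keep], bins=edges)
    return pd.DataFrame(
        {
            "bin_low_met": MET_BIN_EDGES[:-1],
            "bin_high_met": MET_BIN_EDGES[1:],
            "minutes": counts * epoch_s / 60.0,
            "label": met_bin_labels(),
            "category": MET_BIN_CATEGORIES,
        }
    )


def summarize_days(
    epochs: pd.DataFrame,
    sleep_log: SleepLog | None = None,
    epoch_s: float = 6.0,
    min_wear_min: float = 1436.0,
    min_reference_settings: int = 10,
) -> pd.DataFrame:
    """Per-calendar-day summary with the validity decision.

    Requires an epoch table that has been posture-annotated (``is_reference``,
    ``ape_deg``, ``posture`` columns). One row per calendar day containing
    wear minutes, awake wear minutes, the reference-settings count, the
    validity flag, per-bin MET and APE minutes, per-posture minutes and the
    stationary total.
    """
    df = epochs.copy()
    starts = pd.DatetimeIndex(df["start_time"])
    df["_date"] = starts.date
    minutes = epoch_s / 60.0
    rows = []
    for date, day in df.groupby("_date", sort=True):
        wear = day["wear"].to_numpy(dtype=bool)
        awake = awake_mask(day, sleep_log)
        wear_min = wear.sum() * minutes
        settings = int(day["is_reference"].sum()) if "is_reference" in day.columns else 0
        met_hist = build_met_histogram(day, sleep_log, epoch_s)
        ape_hist = build_ape_histogram(day[awake], epoch_s)
        row = {
            "date": pd.Timestamp(date),
            "weekday": pd.Timestamp(date).day_name(),
            "is_weekend": pd.Timestamp(date).dayofweek >= 5,
            "wear_min": wear_min,
            "awake_wear_min": (wear & awake).sum() * minutes,
            "n_reference_settings": settings,
            "valid": bool(wear_min >= min_wear_min and settings >= min_reference_settings),
        }
        for col, m in zip(met_bin_columns(), met_hist["minutes"]):
            row[col] = m
        for col, m in zip(ape_bin_columns(), ape_hist["minutes"]):
            row[col] = m
        postures = day.loc[awake, "posture"] if "posture" in day.columns else pd.Series(dtype="string")
        counts = postures.value_counts()
        for label in POSTURE_LABELS:
            row[f"posture_min_{label}"] = counts.get(label, 0) * minutes
        row["stationary_min"] = float(ape_hist["minutes"].sum())
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ParticipantSummary:
    """Inclusion decision and per-bin mean daily minutes over valid days."""

    included: bool
    n_valid_days: int
    n_days: int
    mean_daily: pd.Series  # mean over valid days of every minutes column
    exclusion_reason: str | None = None


def select_participant(day_summaries: pd.DataFrame, min_valid_days: int = 4) -> ParticipantSummary:
    """Apply the at-least-four-valid-days inclusion rule and average bins."""
    n_days = len(day_summaries)
    if n_days == 0:
        return ParticipantSummary(False, 0, 0, pd.Series(dtype=float), "no monitored days")
    valid = day_summaries[day_summaries["valid"]]
    n_valid = len(valid)
    included = n_valid >= min_valid_days
    minute_cols = [c for c in day_summaries.columns if c.endswith("_min") or "_min_" in c]
    mean_daily = valid[minute_cols].mean() if n_valid else pd.Series(index=minute_cols, dtype=float)
    reason = None
    if not included:
        reason = f"only {n_valid} valid day(s); {min_valid_days} required"
    return ParticipantSummary(included, n_valid, n_days, mean_daily, reason)


def hourly_stationary_profile(
    epochs: pd.DataFrame,
    day_summaries: pd.DataFrame,
    day_type: str = "weekday",
    sleep_log: SleepLog | None = None,
    split_deg: float = 30.0,
    epoch_s: float = 6.0,
) -> pd.DataFrame:
    """Hour-by-hour stationary minutes split at an APE threshold.

    Accumulates, per clock hour, the minutes of stationary (defined-APE,
    awake) time below ``split_deg`` (standing and sitting) and at or above it
    (reclining and lying), averaged over the valid days of the requested type
    (``"weekday"`` or ``"weekend"``).
    """
    if day_type not in ("weekday", "weekend"):
        raise ValueError(f"day_type must be 'weekday' or 'weekend', got {day_type!r}")
    want_weekend = day_type == "weekend"
    valid_dates = {
        d.date() if isinstance(d, pd.Timestamp) else d
        for d in day_summaries.loc[
            day_summaries["valid"] & (day_summaries["is_weekend"] == want_weekend), "date"
        ]
    }
    out = pd.DataFrame(
        {"hour": np.arange(24), "below_split_min": 0.0, "at_least_split_min": 0.0}
    )
    if not valid_dates:
        return out
    starts = pd.DatetimeIndex(epochs["start_time"])
    ape = epochs["ape_deg"].to_numpy(dtype=float)
    keep = (
        np.isfinite(ape)
        & awake_mask(epochs, sleep_log)
        & np.array([t.date() in valid_dates for t in starts])
    )
    minutes = epoch_s / 60.0
    n_days = len(valid_dates)
    hours = starts.hour.to_numpy()
    for h in range(24):
        in_hour = keep & (hours == h)
        out.loc[h, "below_split_min"] = (ape[in_hour] < split_deg).sum() * minutes / n_days
        out.loc[h, "at_least_split_min"] = (ape[in_hour] >= split_deg).sum() * minutes / n_days
    return out
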