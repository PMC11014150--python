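"""Reading and writing raw recordings, epoch tables, sleep logs and cohort tables.

Two raw dialects are supported: delimited text with a header (timestamp as
ISO-8601 or seconds offset, plus x, y, z columns) and a columnar binary table
(Parquet) with the same columns. Proprietary on-device formats are out of
scope. Units must be declared (g or mg); loaded values are normalized to g.
"""

from __future__ import annotations

import pathlib
from typing import Literal

import numpy as np
import pandas as pd
import pydantic

from .errors import ConfigError, DataError, FormatError
from .types import RawRecording, SleepLog


class RawFormat(pydantic.BaseModel):
    """Descriptor for a raw acceleration file.

    ``unit`` declares the stored unit (converted to g on load exactly once);
    ``time_kind`` selects between absolute ISO timestamps and seconds offsets
    (``auto`` sniffs: numeric column means seconds). For seconds offsets the
    absolute start is taken from ``origin``.
    """

    model_config = pydantic.ConfigDict(extra="forbid")

    kind: Literal["csv", "parquet"] = "csv"
    unit: Literal["g", "mg"] = "g"
    time_column: str = "t"
    axis_columns: tuple[str, str, str] = ("x", "y", "z")
    time_kind: Literal["auto", "iso", "seconds"] = "auto"
    origin: str = "2024-01-01T00:00:00"
    delimiter: str = ","
    sampling_rate: float | None = None
    range_g: float = 16.0
    resolution_g: float = 0.004


def _make_format(fmt: RawFormat | dict | None, **overrides) -> RawFormat:
    try:
        if fmt is None:
            return RawFormat(**overrides)
        if isinstance(fmt, dict):
            return RawFormat(**{**fmt, **overrides})
        if overrides:
            return fmt.model_copy(update=overrides)
        return fmt
    except pydantic.ValidationError as exc:  # unknown unit, bad key, ...
        raise ConfigError(str(exc)) from exc


def read_raw_recording(
    path, fmt: RawFormat | dict | None = None, subject_id: str | None = None, **overrides
) -> RawRecording:
    """Load a raw recording, normalizing to g and absolute local timestamps.

    Values outside ``range_g`` are clipped and counted in
    ``RawRecording.n_clipped`` — never silently altered.

    Raises
    ------
    FormatError
        Missing columns or unreadable layout.
    DataError
        Non-monotone (or repeated) timestamps, non-finite values.
    ConfigError
        Unknown unit or inconsistent format options.
    """
    f = _make_format(fmt, **overrides)
    path = pathlib.Path(path)
    if f.kind == "parquet" or path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path, sep=f.delimiter)
    needed = [f.time_column, *f.axis_columns]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")

    tcol = df[f.time_column]
    numeric = pd.api.types.is_numeric_dtype(tcol)
    kind = f.time_kind
    if kind == "auto":
        kind = "seconds" if numeric else "iso"
    if kind == "seconds":
        if not numeric:
            raise FormatError(f"{path}: time column {f.time_column!r} is not numeric seconds")
        offsets = tcol.to_numpy(dtype=float)
        start = pd.Timestamp(f.origin) + pd.to_timedelta(offsets[0], unit="s")
        rel = offsets - offsets[0]
    else:
        try:
            stamps = pd.to_datetime(tcol, format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: cannot parse timestamps: {exc}") from exc
        start = stamps.iloc[0]
        rel = (stamps - start).dt.total_seconds().to_numpy()

    if len(rel) >= 2:
        dt = np.diff(rel)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise DataError(f"{path}: timestamps not strictly increasing at row {bad}")
        rate = 1.0 / float(np.median(dt))
    elif f.sampling_rate is not None:
        rate = f.sampling_rate
    else:
        raise FormatError(f"{path}: single-row file needs an explicit sampling_rate")
    if f.sampling_rate is not None:
        rate = f.sampling_rate

    vals = df[list(f.axis_columns)].to_numpy(dtype=float)
    if f.unit == "mg":
        vals = vals / 1000.0
    if not np.isfinite(vals).all():
        raise DataError(f"{path}: non-finite acceleration values")
    over = np.abs(vals) > f.range_g
    n_clipped = int(over.sum())
    if n_clipped:
        vals = np.clip(vals, -f.range_g, f.range_g)
    return RawRecording(
        start_time=start,
        sampling_rate=rate,
        samples=vals,
        range_g=f.range_g,
        resolution_g=f.resolution_g,
        subject_id=subject_id,
        n_clipped=n_clipped,
    )


def write_raw_recording(rec: RawRecording, path, fmt: RawFormat | dict | None = None, **overrides) -> None:
    """Write a recording in one of the supported dialects (always in g)."""
    f = _make_format(fmt, **overrides)
    if f.unit != "g":
        raise ConfigError("recordings are always written in g; set unit='g'")
    path = pathlib.Path(path)
    df = pd.DataFrame(rec.samples, columns=list(f.axis_columns))
    if f.time_kind == "seconds":
        df.insert(0, f.time_column, np.arange(rec.n_samples) / rec.sampling_rate)
    else:
        df.insert(0, f.time_column, rec.times().strftime("%Y-%m-%dT%H:%M:%S.%f"))
    if f.kind == "parquet" or path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False, sep=f.delimiter)


# ---------------------------------------------------------------------------
# epoch tables

#: Canonical epoch-table columns and their units, written into the header.
EPOCH_COLUMN_UNITS: dict[str, str] = {
    "start_time": "ISO-8601 local time, epoch start (half-open 6 s window)",
    "n_samples": "count",
    "mad_mg": "mg",
    "madxyz_mg": "mg",
    "xave_g": "g",
    "yave_g": "g",
    "zave_g": "g",
    "rave_g": "g",
    "steps": "count",
    "met": "MET",
    "wear": "boolean",
    "is_reference": "boolean",
    "ape_deg": "degrees",
    "posture": "label",
}

#: Columns that must be present for a table to be a valid epoch table.
EPOCH_REQUIRED_COLUMNS = (
    "start_time",
    "n_samples",
    "mad_mg",
    "madxyz_mg",
    "xave_g",
    "yave_g",
    "zave_g",
    "rave_g",
    "steps",
    "met",
    "wear",
)


def write_epoch_table(epochs: pd.DataFrame, path) -> None:
    """Write an epoch table; column names and units are documented in ``#`` header lines."""
    path = pathlib.Path(path)
    df = epochs.copy()
    if "start_time" in df.columns:
        df["start_time"] = pd.DatetimeIndex(df["start_time"]).strftime("%Y-%m-%dT%H:%M:%S.%f")
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
        return
    with open(path, "w") as fh:
        for col in df.columns:
            unit = EPOCH_COLUMN_UNITS.get(col, "unitless")
            fh.write(f"# {col}: {unit}\n")
        df.to_csv(fh, index=False)


def read_epoch_table(path) -> pd.DataFrame:
    """Read an epoch table, validating required columns and parsing dtypes."""
    path = pathlib.Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path, comment="#")
    missing = [c for c in EPOCH_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: epoch table missing column(s) {missing}")
    df["start_time"] = pd.to_datetime(df["start_time"], format="ISO8601")
    df["wear"] = df["wear"].astype(bool)
    if "is_reference" in df.columns:
        df["is_reference"] = df["is_reference"].astype(bool)
    if "posture" in df.columns:
        df["posture"] = df["posture"].astype("string")
    return df


# ---------------------------------------------------------------------------
# sleep logs and cohort tables


def read_sleep_log(path) -> SleepLog:
    """Read a two-column delimited table of (in-bed start, wake time)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: sleep log needs two columns (start, end)")
    starts = pd.to_datetime(df.iloc[:, 0])
    ends = pd.to_datetime(df.iloc[:, 1])
    return SleepLog(list(zip(starts, ends)))


def write_sleep_log(log: SleepLog, path) -> None:
    pd.DataFrame(log.intervals, columns=["in_bed", "wake"]).to_csv(path, index=False)


COHORT_REQUIRED_COLUMNS = ("subject_id", "age", "sex", "bmi")


def read_cohort_table(path) -> pd.DataFrame:
    """Read a per-subject covariate table (age in years, BMI in kg/m^2,
    VO2max in mL/kg/min, plus any per-bin daily-minute columns)."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: cohort table missing column(s) {missing}")
    if (df["age"] < 0).any():
        raise DataError(f"{path}: negative age")
    if (df["bmi"] <= 0).any():
        raise DataError(f"{path}: non-positive BMI")
    return df
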