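"""Core in-memory containers: raw recordings and sleep logs.

Units and conventions
---------------------
Raw acceleration is stored in units of g (1 g = 9.81 m/s^2); intensity
features derived from it are reported in mg (milligravity, 1/1000 g).
Timestamps are naive local clock time: hour-of-day summaries depend on the
wearer's local time, not UTC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass
class RawRecording:
    """A uniformly sampled triaxial acceleration recording.

    Parameters
    ----------
    start_time : timestamp-like
        Local clock time of the first sample.
    sampling_rate : float
        Samples per second (Hz). Must be positive.
    samples : (n, 3) array of float
        Acceleration in g, columns x, y, z.
    range_g : float
        Saturation bound of the sensor; |value| <= range_g for every sample.
    resolution_g : float
        Quantization step of the sensor (informational).
    subject_id : str, optional
        Opaque subject label carried through the pipeline.
    n_clipped : int
        Number of samples that were clipped to ``range_g`` on load. Clipping
        is never silent: loaders count and report it here.
    """

    start_time: pd.Timestamp
    sampling_rate: float
    samples: np.ndarray
    range_g: float = 16.0
    resolution_g: float = 0.004
    subject_id: str | None = None
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.sampling_rate > 0:
            raise DataError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise DataError(f"samples must have shape (n, 3), got {self.samples.shape}")
        if self.samples.shape[0] < 1:
            raise DataError("recording must contain at least one sample")
        if not np.isfinite(self.samples).all():
            raise DataError("samples contain non-finite values")
        if np.abs(self.samples).max() > self.range_g + 1e-9:
            raise DataError(
                f"samples exceed the declared range of +/-{self.range_g} g; "
                "clip on load (with flagging) before constructing a RawRecording"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> pd.DatetimeIndex:
        """Per-sample timestamps (derived from start time and rate)."""
        offsets = np.arange(self.n_samples) / self.sampling_rate
        return self.start_time + pd.to_timedelta(offsets, unit="s")


@dataclass
class SleepLog:
    """Diary of in-bed intervals: ordered, non-overlapping (start, end) pairs."""

    intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = field(default_factory=list)

    def __post_init__(self) -> None:
        iv = [(pd.Timestamp(a), pd.Timestamp(b)) for a, b in self.intervals]
        iv.sort(key=lambda p: p[0])
        for a, b in iv:
            if not a < b:
                raise DataError(f"sleep interval end {b} is not after start {a}")
        for (_, b0), (a1, _) in zip(iv, iv[1:]):
            if a1 < b0:
                raise DataError(f"sleep intervals overlap at {a1}")
        self.intervals = iv

    def in_bed(self, times) -> np.ndarray:
        """Boolean mask: which of ``times`` fall inside an in-bed interval.

        Intervals are half-open: ``start <= t < end``.
        """
        t = pd.DatetimeIndex(times)
        out = np.zeros(len(t), dtype=bool)
        for a, b in self.intervals:
            out |= (t >= a) & (t < b)
        return out

    @property
    def total_hours(self) -> float:
        return sum((b - a).total_seconds() for a, b in self.intervals) / 3600.0
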