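"""Device trigger emulation and wear/non-wear segmentation.

The hip-worn logger collects data through a two-stage trigger: from a
quiescent state it *arms* when the acceleration in any axis departs from a
reference value by more than 187.5 mg, and the arming is *confirmed* (data
collection becomes active) if within the next 5 s the any-axis difference
exceeds 500 mg; otherwise the device returns to the quiescent state. Whenever
an axis exceeds one of these limits, the reference values are updated with the
coincident acceleration values.

Here the same state machine is re-purposed as a software quiescence detector
on continuously recorded files so that the non-wear rule (continuous quiescent
time longer than 120 min) can be applied. Two conventions are fixed by this
module and pinned by tests:

* a confirmed arming marks samples active *from the arming sample onward*;
  an unconfirmed arming window stays quiescent;
* an active bout ends (returns to quiescent) when no arm-level exceedance has
  occurred for one confirmation window (the symmetric counterpart of the
  arming rule; the on-device behavior after activation is not specified).

Thresholds compare with strict inequality ("exceeded").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import RawRecording

ARM_THRESHOLD_MG = 187.5
CONFIRM_THRESHOLD_MG = 500.0
CONFIRM_WINDOW_S = 5.0
NONWEAR_LIMIT_MIN = 120.0


@dataclass
class QuiescenceMask:
    """Per-sample quiescent/active classification of a recording."""

    quiescent: np.ndarray  # (n,) bool
    sampling_rate: float
    start_time: pd.Timestamp

    @property
    def n_samples(self) -> int:
        return len(self.quiescent)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def segments(self) -> pd.DataFrame:
        """Alternating quiescent/active segments partitioning the recording."""
        q = self.quiescent
        edges = np.flatnonzero(np.diff(q.astype(np.int8))) + 1
        bounds = np.concatenate(([0], edges, [len(q)]))
        rows = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            rows.append(
                {
                    "start": self.start_time + pd.Timedelta(seconds=a / self.sampling_rate),
                    "end": self.start_time + pd.Timedelta(seconds=b / self.sampling_rate),
                    "quiescent": bool(q[a]),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class WearSegments:
    """Contiguous, non-overlapping (start, end, wear) segments covering a recording."""

    table: pd.DataFrame  # columns: start, end, wear

    def total_wear_min(self) -> float:
        t = self.table
        sec = (t["end"] - t["start"]).dt.total_seconds()
        return float(sec[t["wear"]].sum() / 60.0)

    def total_nonwear_min(self) -> float:
        t = self.table
        sec = (t["end"] - t["start"]).dt.total_seconds()
        return float(sec[~t["wear"]].sum() / 60.0)

    def nonwear_intervals(self) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
        t = self.table
        return [(r.start, r.end) for r in t[~t["wear"]].itertuples()]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _next_exceedance(a: np.ndarray, ref: np.ndarray, thr: float, start: int, stop: int) -> int:
    """First index in [start, stop) where any-axis |a - ref| > thr, else -1.

    Chunked so long quiescent stretches scan at numpy speed.
    """
    chunk = 1 << 16
    for c0 in range(start, stop, chunk):
        c1 = min(stop, c0 + chunk)
        hit = np.any(np.abs(a[c0:c1] - ref) > thr, axis=1)
        j = int(np.argmax(hit))
        if hit[j]:
            return c0 + j
    return -1


def emulate_trigger(
    raw: RawRecording,
    arm_threshold_mg: float = ARM_THRESHOLD_MG,
    confirm_threshold_mg: float = CONFIRM_THRESHOLD_MG,
    confirm_window_s: float = CONFIRM_WINDOW_S,
) -> QuiescenceMask:
    """Run the trigger state machine over a recording.

    Reference values initialize to the first sample. The confirmation window
    covers the ``round(confirm_window_s * fs)`` samples after the arming
    sample, inclusive of its last sample.
    """
    a = raw.samples
    fs = raw.sampling_rate
    n = raw.n_samples
    arm = arm_threshold_mg / 1000.0
    confirm = confirm_threshold_mg / 1000.0
    w = int(round(confirm_window_s * fs))

    quiescent = np.ones(n, dtype=bool)
    ref = a[0].copy()
    i = 1
    while i < n:
        # quiescent: scan for the next arming exceedance
        j = _next_exceedance(a, ref, arm, i, n)
        if j < 0:
            break
        arm_i = j
        ref = a[j].copy()
        # armed: sequential scan of the confirmation window (reference may update)
        end = min(n, arm_i + w + 1)
        confirmed_at = -1
        k = arm_i + 1
        while k < end:
            d = np.abs(a[k] - ref)
            if (d > confirm).any():
                confirmed_at = k
                ref = a[k].copy()
                break
            if (d > arm).any():
                ref = a[k].copy()
            k += 1
        if confirmed_at < 0:
            i = end  # window expired: stayed quiescent throughout
            continue
        # active: extend while arm-level exceedances keep occurring within one window
        last = confirmed_at
        while True:
            wend = min(n, last + w + 1)
            m = _next_exceedance(a, ref, arm, last + 1, wend)
            if m < 0:
                quiescent[arm_i:wend] = False
                i = wend
                break
            ref = a[m].copy()
            last = m
    return QuiescenceMask(quiescent=quiescent, sampling_rate=fs, start_time=raw.start_time)


def detect_nonwear(mask: QuiescenceMask, limit_min: float = NONWEAR_LIMIT_MIN) -> WearSegments:
    """Mark quiescent runs *strictly longer* than ``limit_min`` as non-wear.

    The per-sample mask is down-sampled to per-second resolution (a second is
    quiescent only if all its samples are) before run lengths are measured.
    A run of exactly ``limit_min`` minutes therefore remains wear.
    """
    q = mask.quiescent
    fs = mask.sampling_rate
    n = len(q)
    sec_idx = np.floor(np.arange(n) / fs).astype(np.int64)
    n_sec = int(sec_idx[-1]) + 1
    starts = np.searchsorted(sec_idx, np.arange(n_sec))
    q_sec = np.minimum.reduceat(q.astype(np.int8), starts).astype(bool)

    nonwear_sec = np.zeros(n_sec, dtype=bool)
    edges = np.flatnonzero(np.diff(q_sec.astype(np.int8))) + 1
    bounds = np.concatenate(([0], edges, [n_sec]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        if q_sec[a] and (b - a) > limit_min * 60.0:
            nonwear_sec[a:b] = True

    wear_sec = ~nonwear_sec
    edges = np.flatnonzero(np.diff(wear_sec.astype(np.int8))) + 1
    bounds = np.concatenate(([0], edges, [n_sec]))
    total = mask.duration_s
    rows = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        end_s = total if b == n_sec else float(b)
        rows.append(
            {
                "start": mask.start_time + pd.Timedelta(seconds=float(a)),
                "end": mask.start_time + pd.Timedelta(seconds=end_s),
                "wear": bool(wear_sec[a]),
            }
        )
    return WearSegments(table=pd.DataFrame(rows))
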