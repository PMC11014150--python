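"""Per-epoch intensity features: MAD, MADxyz, steps, and MET estimation.

Wear time is partitioned into half-open 6 s epochs aligned to the recording
start. For each epoch of samples (x_i, y_i, z_i), i = 1..N, with resultant
r_i = sqrt(x_i^2 + y_i^2 + z_i^2):

    MAD    = (1/N) * sum_i |r_i - R_ave|                       [reported in mg]
    MADxyz = (1/N) * ( sum_i |x_i - X_ave| + sum_i |y_i - Y_ave|
                       + sum_i |z_i - Z_ave| )                 [reported in mg]

where R_ave, X_ave, Y_ave, Z_ave are epoch means. MAD maps to metabolic
equivalents (MET) through a piecewise linear conversion:

    MET = 1.0000 + 0.0223 * MAD        (MAD < 91.5 mg)
    MET = 2.1488 + 0.0093 * MAD        (91.5 mg <= MAD < 500 mg)
    MET = 0.4027 + 0.0107 * MADxyz     (MAD >= 500 mg)

The conversion is implemented exactly as printed; note it has a small
*downward* discontinuity at 91.5 mg (3.0404 from the first piece vs 2.9996
from the second), which is preserved deliberately.

Step counting is not prescribed by the MAD/MET framework; the detector here
band-passes the resultant to the gait band (0.5-3 Hz) and counts maxima with
a 0.25 s refractory period and >= 100 mg prominence, consistent with the
normal-walking criterion of 8-13 steps per 6 s epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal

from .device import WearSegments
from .errors import ConfigError, DataError
from .types import RawRecording

#: Piecewise MET conversion constants: (intercept, slope) per piece.
MET_LOW = (1.0000, 0.0223)  # MAD < 91.5 mg, slope on MAD
MET_MID = (2.1488, 0.0093)  # 91.5 <= MAD < 500 mg, slope on MAD
MET_HIGH = (0.4027, 0.0107)  # MAD >= 500 mg, slope on MADxyz
MET_BREAK_LOW_MG = 91.5
MET_BREAK_HIGH_MG = 500.0

#: Sedentary-behavior gate: epochs below this MAD (i.e. MET < 1.5 by the
#: operational rule) are passed to the posture analysis.
SB_GATE_MAD_MG = 22.5


@dataclass
class EpochBlocks:
    """6 s sample blocks cut from a recording, with wear flags."""

    blocks: np.ndarray  # (n_epochs, samples_per_epoch, 3)
    starts: pd.DatetimeIndex
    wear: np.ndarray  # (n_epochs,) bool
    epoch_s: float
    sampling_rate: float


def epochize(
    raw: RawRecording,
    wear: WearSegments | None = None,
    epoch_s: float = 6.0,
    min_sample_fraction: float = 0.9,
) -> EpochBlocks:
    """Cut a recording into non-overlapping half-open epochs.

    Epochs are aligned to the recording start; a trailing remainder shorter
    than one epoch is dropped. An epoch is flagged ``wear=False`` when it has
    fewer than ``min_sample_fraction`` of the expected samples or overlaps a
    non-wear segment.
    """
    if epoch_s <= 0:
        raise ConfigError(f"epoch_s must be positive, got {epoch_s}")
    n_per = int(round(epoch_s * raw.sampling_rate))
    if n_per < 1:
        raise ConfigError(f"epoch of {epoch_s} s holds no samples at {raw.sampling_rate} Hz")
    n_ep = raw.n_samples // n_per
    blocks = raw.samples[: n_ep * n_per].reshape(n_ep, n_per, 3)
    offsets = np.arange(n_ep) * (n_per / raw.sampling_rate)
    starts = pd.DatetimeIndex(raw.start_time + pd.to_timedelta(offsets, unit="s"))
    wear_flags = np.full(n_ep, n_per >= min_sample_fraction * epoch_s * raw.sampling_rate)
    if wear is not None and n_ep:
        ends = starts + pd.Timedelta(seconds=epoch_s)
        for a, b in wear.nonwear_intervals():
            wear_flags &= ~((starts < b) & (ends > a))
    return EpochBlocks(blocks, starts, wear_flags, epoch_s, raw.sampling_rate)


def compute_mad(block: np.ndarray) -> float:
    """MAD of one sample block, in mg. Undefined (NaN) for fewer than 2 samples."""
    block = np.asarray(block, dtype=float)
    if block.shape[0] < 2:
        return float("nan")
    r = np.linalg.norm(block, axis=1)
    return float(np.mean(np.abs(r - r.mean())) * 1000.0)


def compute_madxyz(block: np.ndarray) -> float:
    """Sum of axis-wise mean absolute deviations, in mg. NaN for fewer than 2 samples."""
    block = np.asarray(block, dtype=float)
    if block.shape[0] < 2:
        return float("nan")
    dev = np.abs(block - block.mean(axis=0))
    return float(dev.mean(axis=0).sum() * 1000.0)


@lru_cache(maxsize=8)
def _gait_filter(fs: float, low: float, high: float):
    return signal.butter(2, (low, high), btype="bandpass", fs=fs, output="sos")


def count_steps(
    block: np.ndarray,
    sampling_rate: float,
    band_hz: tuple[float, float] = (0.5, 3.0),
    refractory_s: float = 0.25,
    prominence_mg: float = 100.0,
) -> int:
    """Count gait-cycle impacts in one block.

    The resultant is band-passed to the gait band and maxima are counted with
    a refractory period and a prominence gate, which keeps low-amplitude
    noise (< ~50 mg) at zero steps.
    """
    block = np.asarray(block, dtype=float)
    if block.shape[0] < 2:
        return 0
    r = np.linalg.norm(block, axis=1)
    r = r - r.mean()
    sos = _gait_filter(float(sampling_rate), *band_hz)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(r) <= padlen:
        return 0
    f = signal.sosfiltfilt(sos, r)
    peaks, _ = signal.find_peaks(
        f,
        distance=max(1, int(round(refractory_s * sampling_rate))),
        prominence=prominence_mg / 1000.0,
    )
    return int(len(peaks))


def estimate_met(mad_mg, madxyz_mg):
    """Piecewise MET estimate from MAD (and, at high intensity, MADxyz).

    Accepts scalars or arrays; raises :class:`DataError` on negative inputs.
    """
    mad = np.asarray(mad_mg, dtype=float)
    mxyz = np.asarray(madxyz_mg, dtype=float)
    if np.any(mad[np.isfinite(mad)] < 0) or np.any(mxyz[np.isfinite(mxyz)] < 0):
        raise DataError("MAD and MADxyz must be non-negative")
    met = np.where(
        mad < MET_BREAK_LOW_MG,
        MET_LOW[0] + MET_LOW[1] * mad,
        np.where(
            mad < MET_BREAK_HIGH_MG,
            MET_MID[0] + MET_MID[1] * mad,
            MET_HIGH[0] + MET_HIGH[1] * mxyz,
        ),
    )
    met = np.where(np.isfinite(mad), met, np.nan)
    if np.ndim(mad_mg) == 0 and np.ndim(madxyz_mg) == 0:
        return float(met)
    return met


def compute_epoch_table(
    raw: RawRecording,
    wear: WearSegments | None = None,
    epoch_s: float = 6.0,
    min_sample_fraction: float = 0.9,
    step_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Full per-epoch feature table for a recording.

    Columns: start_time, n_samples, mad_mg, madxyz_mg, xave_g, yave_g,
    zave_g, rave_g, steps, met, wear.
    """
    eb = epochize(raw, wear, epoch_s, min_sample_fraction)
    blocks = eb.blocks
    n_ep, n_per, _ = blocks.shape
    if n_ep == 0:
        cols = list(
            (
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
        )
        return pd.DataFrame(columns=cols)
    r = np.linalg.norm(blocks, axis=2)  # (E, n)
    rave = r.mean(axis=1)
    mad = np.abs(r - rave[:, None]).mean(axis=1) * 1000.0
    mean_vec = blocks.mean(axis=1)  # (E, 3)
    madxyz = np.abs(blocks - mean_vec[:, None, :]).mean(axis=1).sum(axis=1) * 1000.0
    kw = step_kwargs or {}
    steps = np.array([count_steps(blocks[i], eb.sampling_rate, **kw) for i in range(n_ep)])
    met = estimate_met(mad, madxyz)
    return pd.DataFrame(
        {
            "start_time": eb.starts,
            "n_samples": n_per,
            "mad_mg": mad,
            "madxyz_mg": madxyz,
            "xave_g": mean_vec[:, 0],
            "yave_g": mean_vec[:, 1],
            "zave_g": mean_vec[:, 2],
            "rave_g": rave,
            "steps": steps,
            "met": met,
            "wear": eb.wear,
        }
    )
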