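"""Walking-referenced posture estimation (APE).

The posture angle APE exploits two facts: Earth's gravity is constant, and
walking posture is upright. For each 6 s epoch the mean acceleration vector,
normalized to unit length, gives the device orientation

    e_hat = (X_ave, Y_ave, Z_ave) / ||(X_ave, Y_ave, Z_ave)||

An epoch is recognized as normal walking when its MAD lies in 150-350 mg, it
contains 8-13 steps, and the steadiness ratio MADxyz / MAD is below 1.6.
Every walking epoch's e_hat becomes the new upright reference vector u_hat;
for any later stationary epoch the posture angle is

    APE = arccos( e_hat . u_hat )    (degrees, in [0, 180])

Stationary epochs (MAD below the 22.5 mg sedentary gate) are classified by
APE cut-points: standing below 11.6 deg, sitting 11.6-30 deg, reclining
30-73.9 deg, lying at 73.9 deg and above. The stationary time distribution is
summarized in 18 histogram bins of 5 deg (the last bin open-ended at 85 deg);
each bin also carries a descriptive annotation (standing below 10 deg,
standing/sitting transition 10-15 deg, desk sitting 15-30 deg, sofa sitting
30-55 deg, sitting/lying transition 55-75 deg, lying from 75 deg up).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import SB_GATE_MAD_MG


@dataclass(frozen=True)
class WalkingCriteria:
    """Limits for recognizing a normal-walking reference epoch."""

    mad_min_mg: float = 150.0
    mad_max_mg: float = 350.0
    steps_min: int = 8
    steps_max: int = 13
    steadiness_max: float = 1.6  # strict: MADxyz/MAD must be < this


@dataclass(frozen=True)
class PostureCutpoints:
    """APE cut-points (degrees) for the four-way posture classification."""

    stand_sit: float = 11.6
    sit_recline: float = 30.0
    recline_lie: float = 73.9


#: 18 histogram bins of 5 degrees; the last bin is open-ended at 85 degrees.
APE_BIN_EDGES = np.concatenate([np.arange(0.0, 90.0, 5.0), [np.inf]])

#: Descriptive annotation of each histogram bin (behavioral reading of the range).
APE_BIN_DESCRIPTIVE = (
    ["standing"] * 2
    + ["transition_standing_sitting"]
    + ["desk_sitting"] * 3
    + ["sofa_sitting"] * 5
    + ["transition_sitting_lying"] * 4
    + ["lying"] * 3
)

POSTURE_LABELS = ("standing", "sitting", "reclining", "lying")


def ape_bin_labels() -> list[str]:
    """Short labels for the 18 APE bins: '00_05', ..., '80_85', '85_up'."""
    labels = [f"{int(lo):02d}_{int(hi):02d}" for lo, hi in zip(APE_BIN_EDGES[:-2], APE_BIN_EDGES[1:-1])]
    labels.append("85_up")
    return labels


def orientation_vector(mean_vector) -> np.ndarray:
    """Unit device-orientation vector from an epoch's mean acceleration.

    Returns an all-NaN vector when the mean has zero norm (undefined
    orientation).
    """
    v = np.asarray(mean_vector, dtype=float)
    n = np.linalg.norm(v)
    if n == 0 or not np.isfinite(n):
        return np.full(3, np.nan)
    return v / n


def is_walking_reference(mad_mg, steps, madxyz_mg, criteria: WalkingCriteria | None = None):
    """True where an epoch satisfies all three normal-walking criteria.

    The intensity and step limits are inclusive; the steadiness ratio is a
    strict upper bound (a ratio of exactly 1.6 does not qualify).
    """
    c = criteria or WalkingCriteria()
    mad = np.asarray(mad_mg, dtype=float)
    st = np.asarray(steps)
    mxyz = np.asarray(madxyz_mg, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mad > 0, mxyz / mad, np.inf)
    ok = (
        (mad >= c.mad_min_mg)
        & (mad <= c.mad_max_mg)
        & (st >= c.steps_min)
        & (st <= c.steps_max)
        & (ratio < c.steadiness_max)
    )
    if np.ndim(mad_mg) == 0:
        return bool(ok)
    return ok


def compute_ape(e_hat, u_hat) -> float:
    """Angle between the orientation and reference vectors, in degrees.

    The inner product is clamped to [-1, 1] before arccos to absorb rounding.
    """
    e = np.asarray(e_hat, dtype=float)
    u = np.asarray(u_hat, dtype=float)
    dot = np.clip(np.sum(e * u, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(dot))


def classify_posture(ape_deg, cutpoints: PostureCutpoints | None = None):
    """Map a defined APE value to standing / sitting / reclining / lying."""
    c = cutpoints or PostureCutpoints()
    ape = np.asarray(ape_deg, dtype=float)
    out = np.select(
        [ape < c.stand_sit, ape < c.sit_recline, ape < c.recline_lie],
        ["standing", "sitting", "reclining"],
        default="lying",
    )
    out = np.where(np.isfinite(ape), out, "undefined")
    if np.ndim(ape_deg) == 0:
        return str(out)
    return out


def track_reference(
    epochs: pd.DataFrame,
    criteria: WalkingCriteria | None = None,
    backfill: bool = False,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Assign the upright reference vector to every epoch.

    The reference for an epoch is the orientation of the most recent
    qualifying walking epoch (last-value-forward). Epochs before the first
    setting carry an undefined reference unless ``backfill`` is set, in which
    case the first setting is propagated backwards (whole-file batch use).

    Returns
    -------
    u : (n, 3) array
        Per-epoch reference vector (NaN rows where undefined).
    is_reference : (n,) bool array
        Which epochs set the reference.
    settings : DataFrame
        Log of settings: time, ux, uy, uz.
    """
    mv = epochs[["xave_g", "yave_g", "zave_g"]].to_numpy(dtype=float)
    norms = np.linalg.norm(mv, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_hat = np.where(norms[:, None] > 0, mv / np.where(norms == 0, 1.0, norms)[:, None], np.nan)
    walking = is_walking_reference(
        epochs["mad_mg"].to_numpy(), epochs["steps"].to_numpy(), epochs["madxyz_mg"].to_numpy(), criteria
    )
    walking = np.asarray(walking) & epochs["wear"].to_numpy(dtype=bool) & (norms > 0)

    n = len(epochs)
    idx = np.where(walking, np.arange(n), -1)
    idx = np.maximum.accumulate(idx)
    if backfill and walking.any():
        first = int(np.flatnonzero(walking)[0])
        idx = np.where(idx < 0, first, idx)
    u = np.full((n, 3), np.nan)
    defined = idx >= 0
    u[defined] = e_hat[idx[defined]]

    settings = pd.DataFrame(
        {
            "time": pd.DatetimeIndex(epochs["start_time"])[walking],
            "ux": e_hat[walking, 0],
            "uy": e_hat[walking, 1],
            "uz": e_hat[walking, 2],
        }
    )
    return u, walking, settings


def annotate_postures(
    epochs: pd.DataFrame,
    sb_gate_mg: float = SB_GATE_MAD_MG,
    criteria: WalkingCriteria | None = None,
    cutpoints: PostureCutpoints | None = None,
    backfill: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add APE and posture columns to an epoch table.

    APE is computed for worn stationary epochs (MAD below the sedentary gate)
    once a reference is available; other epochs carry NaN / 'undefined'.
    Returns the augmented copy of the table and the reference-settings log.
    """
    df = epochs.copy()
    u, walking, settings = track_reference(df, criteria, backfill)
    mv = df[["xave_g", "yave_g", "zave_g"]].to_numpy(dtype=float)
    norms = np.linalg.norm(mv, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_hat = mv / np.where(norms == 0, np.nan, norms)[:, None]
    stationary = (
        df["wear"].to_numpy(dtype=bool)
        & (df["mad_mg"].to_numpy(dtype=float) < sb_gate_mg)
        & (norms > 0)
        & ~np.isnan(u[:, 0])
    )
    ape = np.full(len(df), np.nan)
    if stationary.any():
        ape[stationary] = compute_ape(e_hat[stationary], u[stationary])
    df["is_reference"] = walking
    df["ape_deg"] = ape
    posture = classify_posture(ape, cutpoints)
    df["posture"] = pd.array(np.where(np.isfinite(ape), posture, pd.NA), dtype="string")
    return df, settings


def build_ape_histogram(epochs: pd.DataFrame, epoch_s: float = 6.0) -> pd.DataFrame:
    """Minutes of stationary time per 5-degree APE bin (18 bins).

    Every epoch with a defined APE contributes ``epoch_s / 60`` minutes; bin
    minutes therefore sum to the stationary time with defined APE.
    """
    ape = epochs["ape_deg"].to_numpy(dtype=float)
    ape = ape[np.isfinite(ape)]
    edges = APE_BIN_EDGES.copy()
    edges[-1] = 181.0  # APE is bounded by 180 deg; close the open bin for histogramming
    counts, _ = np.histogram(ape, bins=edges)
    return pd.DataFrame(
        {
            "bin_low_deg": APE_BIN_EDGES[:-1],
            "bin_high_deg": APE_BIN_EDGES[1:],
            "minutes": counts * epoch_s / 60.0,
            "label": ape_bin_labels(),
            "descriptive": APE_BIN_DESCRIPTIVE,
        }
    )
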