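"""Synthetic hip-worn recordings and cohorts with known ground truth.

The generator scripts a day as ordered activity segments (standing, desk
sitting, sofa sitting, lying, walking, non-wear). Each segment orients the
1 g gravity vector at its scripted tilt from the upright reference; walking
adds a sinusoid at the scripted cadence along the body-vertical axis plus a
smaller double-frequency harmonic on the anteroposterior axis, with the
amplitude calibrated so the realized epoch MAD hits the target within a few
percent. A fixed mount rotation composes with everything, white sensor noise
is added, and the signal is quantized to the 0.004 g sensor step and clipped
at +/-16 g. Non-wear segments emit exactly constant gravity.

Worn stationary segments additionally receive sparse 1 s "fidget" pulses
(default every 30 min): real wearers produce micro-movements, and without
them any still posture longer than the 120 min quiescence limit would be
misread as non-wear.

The cohort generator draws covariates (age, sex, BMI, VO2max) with realistic
dependence and plants monotone effects of BMI and fitness on the per-bin
stationary minutes, so correlation-recovery tests have a known truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import ConfigError
from .features import compute_mad
from .summaries import ape_bin_columns
from .types import RawRecording

ACTIVITIES = ("standing", "desk_sitting", "sofa_sitting", "lying", "walking", "nonwear")

#: Scripted stationary activities and the tilt (degrees from upright) they
#: typically occupy in the synthetic schedules.
TYPICAL_TILTS = {"standing": 0.0, "desk_sitting": 20.0, "sofa_sitting": 45.0, "lying": 85.0}


@dataclass
class Segment:
    """One scripted activity segment.

    ``tilt_deg`` is the device tilt from the upright (walking) orientation;
    ``cadence_hz`` (steps per second) and ``target_mad_mg`` apply to walking
    segments only; ``noise_mg`` is the white-noise standard deviation.
    """

    duration_s: float
    activity: str
    tilt_deg: float = 0.0
    cadence_hz: float = 0.0
    target_mad_mg: float = 0.0
    noise_mg: float = 5.0

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ConfigError(f"unknown activity {self.activity!r}; one of {ACTIVITIES}")
        if not self.duration_s > 0:
            raise ConfigError("segment duration must be positive")
        if not 0.0 <= self.tilt_deg <= 180.0:
            raise ConfigError("tilt_deg must lie in [0, 180]")
        if self.activity == "walking":
            if not self.cadence_hz > 0:
                raise ConfigError("walking segments need a positive cadence")
            if not (150.0 <= self.target_mad_mg <= 350.0):
                warnings.warn(
                    f"walking target MAD {self.target_mad_mg} mg is outside the 150-350 mg "
                    "normal-walking band; such epochs may not qualify as reference settings"
                )
        elif self.cadence_hz > 0:
            raise ConfigError("cadence applies to walking segments only")


def walking(duration_s: float, cadence_hz: float = 1.8, target_mad_mg: float = 250.0, noise_mg: float = 5.0) -> Segment:
    return Segment(duration_s, "walking", 0.0, cadence_hz, target_mad_mg, noise_mg)


def stationary(activity: str, duration_s: float, tilt_deg: float | None = None, noise_mg: float = 5.0) -> Segment:
    tilt = TYPICAL_TILTS.get(activity, 0.0) if tilt_deg is None else tilt_deg
    return Segment(duration_s, activity, tilt, 0.0, 0.0, noise_mg)


def read_schedule(path) -> list[Segment]:
    df = pd.read_csv(path)
    return [
        Segment(
            float(r.duration_s),
            str(r.activity),
            float(getattr(r, "tilt_deg", 0.0)),
            float(getattr(r, "cadence_hz", 0.0)),
            float(getattr(r, "target_mad_mg", 0.0)),
            float(getattr(r, "noise_mg", 0.0)),
        )
        for r in df.itertuples()
    ]


def write_schedule(schedule: list[Segment], path) -> None:
    pd.DataFrame([vars(s) for s in schedule]).to_csv(path, index=False)


def _tilt_matrix(tilt_deg: float) -> np.ndarray:
    # rotation of the device about the mediolateral (y) axis
    return Rotation.from_euler("y", tilt_deg, degrees=True).as_matrix()


def calibrate_walk_amplitude(
    target_mad_mg: float,
    cadence_hz: float,
    sampling_rate: float,
    harmonic_fraction: float = 0.3,
    epoch_s: float = 6.0,
) -> float:
    """Oscillation amplitude (g) whose realized epoch MAD matches the target.

    Starts from the closed form for a pure sinusoid (MAD = 2A/pi) and refines
    by measuring the realized MAD of the noise-free gait signal.
    """
    amp = (np.pi / 2.0) * target_mad_mg / 1000.0
    t = np.arange(int(round(epoch_s * sampling_rate))) / sampling_rate
    for _ in range(6):
        sig = np.column_stack(
            [
                harmonic_fraction * amp * np.sin(4 * np.pi * cadence_hz * t),
                np.zeros_like(t),
                1.0 + amp * np.sin(2 * np.pi * cadence_hz * t),
            ]
        )
        realized = compute_mad(sig)
        if realized <= 0:
            break
        amp *= target_mad_mg / realized
    return float(amp)


def generate_recording(
    schedule: list[Segment],
    mount_rotation: np.ndarray | None = None,
    seed: int = 0,
    sampling_rate: float = 100.0,
    start_time="2024-01-01T00:00:00",
    quantize: bool = True,
    clip: bool = True,
    range_g: float = 16.0,
    resolution_g: float = 0.004,
    subject_id: str = "synthetic",
    fidget_interval_s: float = 1800.0,
    fidget_amp_g: float = 0.8,
    harmonic_fraction: float = 0.3,
    epoch_s: float = 6.0,
) -> tuple[RawRecording, pd.DataFrame]:
    """Render a schedule into a raw recording plus per-epoch truth labels.

    Truth rows are aligned to the same half-open ``epoch_s`` grid the feature
    pipeline uses; each epoch is labeled by the segment covering its
    midpoint.
    """
    if not schedule:
        raise ConfigError("schedule must contain at least one segment")
    rng = np.random.default_rng(seed)
    fs = sampling_rate
    mount = np.eye(3) if mount_rotation is None else np.asarray(mount_rotation, dtype=float)
    if mount.shape != (3, 3):
        raise ConfigError("mount_rotation must be a 3x3 rotation matrix")

    chunks = []
    bounds = [0.0]
    for seg in schedule:
        n = int(round(seg.duration_s * fs))
        t = np.arange(n) / fs
        if seg.activity == "walking":
            amp = calibrate_walk_amplitude(seg.target_mad_mg, seg.cadence_hz, fs, harmonic_fraction, epoch_s)
            upright = np.column_stack(
                [
                    harmonic_fraction * amp * np.sin(4 * np.pi * seg.cadence_hz * t),
                    np.zeros(n),
                    1.0 + amp * np.sin(2 * np.pi * seg.cadence_hz * t),
                ]
            )
        else:
            upright = np.tile([0.0, 0.0, 1.0], (n, 1))
        body = upright @ _tilt_matrix(seg.tilt_deg).T

        if seg.activity not in ("nonwear", "walking") and fidget_interval_s > 0:
            k = 1
            while k * fidget_interval_s < seg.duration_s:
                at = k * fidget_interval_s + rng.uniform(-60.0, 60.0)
                i0 = int(np.clip(at * fs, 0, n - 1))
                i1 = int(min(n, i0 + round(fs)))  # 1 s pulse
                body[i0:i1, 0] += fidget_amp_g
                k += 1
        if seg.activity != "nonwear" and seg.noise_mg > 0:
            body = body + rng.normal(0.0, seg.noise_mg / 1000.0, size=(n, 3))
        chunks.append(body @ mount.T)
        bounds.append(bounds[-1] + seg.duration_s)

    samples = np.concatenate(chunks, axis=0)
    if quantize:
        samples = np.round(samples / resolution_g) * resolution_g
    n_clipped = 0
    if clip:
        over = np.abs(samples) > range_g
        n_clipped = int(over.sum())
        samples = np.clip(samples, -range_g, range_g)
    rec = RawRecording(
        start_time=pd.Timestamp(start_time),
        sampling_rate=fs,
        samples=samples,
        range_g=range_g,
        resolution_g=resolution_g,
        subject_id=subject_id,
        n_clipped=n_clipped,
    )

    n_ep = rec.n_samples // int(round(epoch_s * fs))
    mids = (np.arange(n_ep) + 0.5) * epoch_s
    seg_idx = np.clip(np.searchsorted(bounds, mids, side="right") - 1, 0, len(schedule) - 1)
    truth = pd.DataFrame(
        {
            "start_time": rec.start_time + pd.to_timedelta(np.arange(n_ep) * epoch_s, unit="s"),
            "activity": [schedule[i].activity for i in seg_idx],
            "tilt_deg": [schedule[i].tilt_deg for i in seg_idx],
        }
    )
    return rec, truth


def daily_routine_schedule(noise_mg: float = 5.0) -> list[Segment]:
    """A plausible 24 h weekday: night in bed, commute walks, desk work with
    hourly walk breaks, an evening on the sofa. Exactly 86400 s long, with
    enough walking bouts to set the reference vector well over 10 times."""
    sched: list[Segment] = [stationary("lying", 7 * 3600, noise_mg=noise_mg)]
    sched += [walking(180, noise_mg=noise_mg), stationary("standing", 1620, noise_mg=noise_mg)]
    for _ in range(8):  # working hours: 54 min at the desk, 3 min walk, 3 min standing
        sched += [
            stationary("desk_sitting", 3240, noise_mg=noise_mg),
            walking(180, noise_mg=noise_mg),
            stationary("standing", 180, noise_mg=noise_mg),
        ]
    sched += [walking(600, noise_mg=noise_mg), stationary("standing", 1800, noise_mg=noise_mg)]
    for _ in range(3):  # evening: sofa with short breaks
        sched += [stationary("sofa_sitting", 3300, noise_mg=noise_mg), walking(120, noise_mg=noise_mg)]
    used = sum(s.duration_s for s in sched)
    sched.append(stationary("lying", 86400 - used, noise_mg=noise_mg))
    return sched


@dataclass
class CohortEffects:
    """Planted monotone effects on per-bin stationary minutes.

    ``bmi_effect_min`` / ``crf_effect_min`` are minutes per standard deviation
    of the covariate at a reference-size bin; low-angle bins (< 25 deg) move
    *up* with fitness and *down* with BMI, high-angle bins (>= 30 deg) the
    opposite, matching the upright-posture physiology the pipeline is meant
    to resolve.
    """

    bmi_effect_min: float = 20.0
    crf_effect_min: float = 20.0

    def __post_init__(self) -> None:
        for v in (self.bmi_effect_min, self.crf_effect_min):
            if not np.isfinite(v) or v < 0:
                raise ConfigError("effect sizes must be finite and non-negative")


#: Baseline mean daily minutes in each of the 18 APE bins (sums to ~740 min of
#: stationary time, weighted toward standing angles as in population data).
BASE_BIN_MINUTES = np.array(
    [170, 130, 55, 50, 45, 35, 32, 30, 28, 26, 24, 18, 16, 12, 10, 20, 25, 15], dtype=float
)

#: Direction of the planted fitness effect per bin (+1 below 25 deg, 0 for
#: the 25-30 deg transition, -1 at 30 deg and above). BMI uses the negation.
EFFECT_SIGNS_CRF = np.array([1, 1, 1, 1, 1, 0, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1], dtype=float)


def generate_cohort(
    n: int = 300,
    effects: CohortEffects | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic cohort with covariates and per-bin daily stationary minutes.

    Ages are uniform on 20-69 with balanced sexes; BMI is normal around
    26.5 kg/m^2; VO2max declines with age and BMI around sex-specific levels.
    Per-bin minutes start from :data:`BASE_BIN_MINUTES` and receive the
    planted monotone effects plus lognormal-ish day-to-day noise, clipped at
    zero. Deterministic under ``seed``.
    """
    if n < 10:
        raise ConfigError(f"cohort size must be at least 10, got {n}")
    eff = effects or CohortEffects()
    rng = np.random.default_rng(seed)

    sex = np.array(["female", "male"])[np.arange(n) % 2]
    rng.shuffle(sex)
    age = rng.uniform(20.0, 69.0, size=n)
    bmi = np.clip(rng.normal(26.5, 4.0, size=n), 17.0, 45.0)
    sex_base = np.where(sex == "male", 40.0, 34.0)
    vo2max = sex_base - 0.25 * (age - 45.0) - 0.8 * (bmi - 26.5) + rng.normal(0.0, 3.5, size=n)
    vo2max = np.clip(vo2max, 10.0, 60.0)

    z_bmi = (bmi - bmi.mean()) / bmi.std()
    z_vo2 = np.empty(n)
    for s in ("female", "male"):
        m = sex == s
        z_vo2[m] = (vo2max[m] - vo2max[m].mean()) / vo2max[m].std()

    scale = BASE_BIN_MINUTES / BASE_BIN_MINUTES.mean()
    signs = EFFECT_SIGNS_CRF
    minutes = (
        BASE_BIN_MINUTES[None, :]
        + signs[None, :] * scale[None, :] * (eff.crf_effect_min * z_vo2[:, None] - eff.bmi_effect_min * z_bmi[:, None])
        + rng.normal(0.0, 0.12 * BASE_BIN_MINUTES[None, :], size=(n, 18))
    )
    minutes = np.clip(minutes, 0.0, None)

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "vo2max": vo2max,
        }
    )
    for j, col in enumerate(ape_bin_columns()):
        df[col] = minutes[:, j]
    return df
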