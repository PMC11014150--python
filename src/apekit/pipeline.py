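"""End-to-end pipeline: raw recording -> epoch table -> day summaries ->
participant summary + JSON run report.

Every stage is deterministic given the configuration; all summary numbers
are reproducible from the epoch table alone (no hidden state)."""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass

import pandas as pd

from . import __version__
from .config import RunConfig
from .device import detect_nonwear, emulate_trigger
from .errors import ApekitError
from .features import compute_epoch_table
from .posture import PostureCutpoints, WalkingCriteria, annotate_postures
from .raw_io import write_epoch_table
from .summaries import select_participant, summarize_days
from .types import RawRecording, SleepLog


@dataclass
class PipelineResult:
    epochs: pd.DataFrame
    day_summaries: pd.DataFrame
    participant: object  # ParticipantSummary
    settings: pd.DataFrame
    report: dict


def _stage(name: str):
    """Decorate pipeline stages so errors carry their stage name."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ApekitError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc

        return inner

    return wrap


def run_pipeline(
    config: RunConfig,
    raw: RawRecording,
    sleep_log: SleepLog | None = None,
    out_dir=None,
) -> PipelineResult:
    """Run trigger emulation, feature extraction, posture annotation and
    summaries over one recording; optionally write the result tables."""
    criteria = WalkingCriteria(
        mad_min_mg=config.walking.mad_min_mg,
        mad_max_mg=config.walking.mad_max_mg,
        steps_min=config.walking.steps_min,
        steps_max=config.walking.steps_max,
        steadiness_max=config.walking.steadiness_max,
    )
    cutpoints = PostureCutpoints(
        stand_sit=config.cutpoints.stand_sit,
        sit_recline=config.cutpoints.sit_recline,
        recline_lie=config.cutpoints.recline_lie,
    )
    step_kwargs = {
        "band_hz": (config.steps.band_low_hz, config.steps.band_high_hz),
        "refractory_s": config.steps.refractory_s,
        "prominence_mg": config.steps.prominence_mg,
    }

    mask = _stage("trigger")(emulate_trigger)(
        raw,
        arm_threshold_mg=config.trigger.arm_threshold_mg,
        confirm_threshold_mg=config.trigger.confirm_threshold_mg,
        confirm_window_s=config.trigger.confirm_window_s,
    )
    wear = _stage("nonwear")(detect_nonwear)(mask, config.nonwear_limit_min)
    epochs = _stage("features")(compute_epoch_table)(
        raw, wear, config.epoch_s, config.min_sample_fraction, step_kwargs
    )
    epochs, settings = _stage("posture")(annotate_postures)(
        epochs, config.sb_gate_mg, criteria, cutpoints, config.backfill_reference
    )
    days = _stage("summaries")(summarize_days)(
        epochs,
        sleep_log,
        config.epoch_s,
        config.validity.min_wear_min,
        config.validity.min_reference_settings,
    )
    participant = select_participant(days, config.validity.min_valid_days)

    daily_settings = {
        str(r.date.date()): int(r.n_reference_settings) for r in days.itertuples()
    }
    exclusions = []
    for r in days.itertuples():
        if not r.valid:
            why = []
            if r.wear_min < config.validity.min_wear_min:
                why.append(f"wear {r.wear_min:.1f} min < {config.validity.min_wear_min}")
            if r.n_reference_settings < config.validity.min_reference_settings:
                why.append(
                    f"{r.n_reference_settings} reference settings < "
                    f"{config.validity.min_reference_settings}"
                )
            exclusions.append({"date": str(r.date.date()), "reasons": why})
    report = {
        "version": __version__,
        "subject_id": raw.subject_id,
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "n_samples": raw.n_samples,
        "n_clipped": raw.n_clipped,
        "n_epochs": len(epochs),
        "total_wear_min": wear.total_wear_min(),
        "total_nonwear_min": wear.total_nonwear_min(),
        "daily_reference_settings": daily_settings,
        "invalid_days": exclusions,
        "included": bool(participant.included),
        "n_valid_days": int(participant.n_valid_days),
        "exclusion_reason": participant.exclusion_reason,
    }

    if out_dir is not None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_epoch_table(epochs, out / "epochs.csv")
        days.to_csv(out / "day_summaries.csv", index=False)
        participant.mean_daily.rename("mean_daily_min").to_csv(out / "participant_means.csv")
        (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return PipelineResult(epochs, days, participant, settings, report)
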