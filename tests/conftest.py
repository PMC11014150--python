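import numpy as np
import pandas as pd
import pytest

from apekit.config import RunConfig
from apekit.pipeline import run_pipeline
from apekit.synthetic import Segment, generate_recording, stationary, walking
from apekit.types import RawRecording, SleepLog


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


def make_recording(samples, fs=100.0, start="2024-01-01T00:00:00", **kw):
    return RawRecording(start_time=start, sampling_rate=fs, samples=np.asarray(samples, float), **kw)


@pytest.fixture
def noise_free_schedule():
    """Walking first (sets the reference), then one segment per posture."""
    return [
        walking(120, noise_mg=0.0),
        stationary("standing", 600, noise_mg=0.0),
        stationary("desk_sitting", 600, noise_mg=0.0),
        walking(60, noise_mg=0.0),
        stationary("sofa_sitting", 600, noise_mg=0.0),
        stationary("lying", 600, noise_mg=0.0),
    ]


@pytest.fixture(scope="session")
def short_day_result():
    """A few hours of mixed behavior (with a non-wear gap) through the full pipeline.

    Session-scoped: several tests assert different invariants on the same run.
    """
    segs = [
        walking(300),
        stationary("desk_sitting", 3600),
        walking(120),
        stationary("sofa_sitting", 1800),
        Segment(130 * 60.0, "nonwear", tilt_deg=45.0),
        walking(120),
        stationary("lying", 3600),
    ]
    rec, truth = generate_recording(segs, seed=7, sampling_rate=25.0)
    sleep = SleepLog(
        [(rec.start_time + pd.Timedelta(hours=4), rec.start_time + pd.Timedelta(hours=4.5))]
    )
    result = run_pipeline(RunConfig(), rec, sleep)
    return {"recording": rec, "truth": truth, "sleep": sleep, "result": result}
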