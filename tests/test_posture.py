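"""Walking recognition, reference tracking, APE computation and posture labels."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from apekit.config import RunConfig
from apekit.device import detect_nonwear, emulate_trigger
from apekit.features import compute_epoch_table
from apekit.pipeline import run_pipeline
from apekit.posture import (
    APE_BIN_EDGES,
    PostureCutpoints,
    annotate_postures,
    build_ape_histogram,
    classify_posture,
    compute_ape,
    is_walking_reference,
    orientation_vector,
    track_reference,
)
from apekit.synthetic import generate_recording, stationary, walking
from apekit.types import RawRecording


def epoch_frame(rows):
    """Minimal epoch table from (mad, steps, madxyz, mean_vec) tuples."""
    df = pd.DataFrame(
        {
            "start_time": pd.date_range("2024-01-01", periods=len(rows), freq="6s"),
            "mad_mg": [r[0] for r in rows],
            "steps": [r[1] for r in rows],
            "madxyz_mg": [r[2] for r in rows],
            "xave_g": [r[3][0] for r in rows],
            "yave_g": [r[3][1] for r in rows],
            "zave_g": [r[3][2] for r in rows],
            "wear": True,
        }
    )
    return df


WALK = (250.0, 10, 300.0)  # qualifying walking features
STILL = (5.0, 0, 8.0)  # stationary features below the sedentary gate


class TestOrientationVector:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ((0, 0, 1), (0, 0, 1)),
            ((0, 0, 2), (0, 0, 1)),
            ((1, 1, 0), (np.sqrt(2) / 2, np.sqrt(2) / 2, 0)),
        ],
    )
    def test_normalization(self, vec, expected):
        np.testing.assert_allclose(orientation_vector(vec), expected, atol=1e-12)

    def test_zero_norm_undefined(self):
        assert np.isnan(orientation_vector((0, 0, 0))).all()


class TestWalkingRecognition:
    @pytest.mark.parametrize(
        "mad,steps,madxyz,expected",
        [
            (250, 10, 300, True),  # ratio 1.2, everything within limits
            (400, 10, 480, False),  # MAD outside 150-350
            (250, 10, 400, False),  # ratio exactly 1.6: strict bound
            (250, 7, 300, False),  # too few steps
            (250, 14, 300, False),  # too many steps
            (150, 8, 239, True),  # inclusive lower limits
            (350, 13, 350, True),  # inclusive upper limits
        ],
    )
    def test_criteria(self, mad, steps, madxyz, expected):
        assert is_walking_reference(mad, steps, madxyz) is expected


class TestTrackReference:
    def test_no_walking_leaves_reference_undefined(self):
        df = epoch_frame([(*STILL, (0, 0, 1))] * 5)
        u, walking_flags, settings = track_reference(df)
        assert np.isnan(u).all()
        assert not walking_flags.any()
        assert len(settings) == 0

    def test_last_value_carried_forward(self):
        df = epoch_frame([(*STILL, (0, 0, 1)), (*WALK, (0, 0, 1)), (*STILL, (0, 1, 0))])
        u, walking_flags, settings = track_reference(df)
        assert np.isnan(u[0]).all()  # before the first setting
        np.testing.assert_allclose(u[1], [0, 0, 1])
        np.testing.assert_allclose(u[2], [0, 0, 1])
        assert len(settings) == 1

    def test_new_setting_changes_ape_of_fixed_posture(self):
        tilted = (0, np.sin(0.3), np.cos(0.3))
        df = epoch_frame(
            [
                (*WALK, (0, 0, 1)),
                (*STILL, (0, 1, 0)),
                (*WALK, tilted),
                (*STILL, (0, 1, 0)),
            ]
        )
        out, _ = annotate_postures(df)
        ape = out["ape_deg"].to_numpy()
        assert ape[1] == pytest.approx(90.0)
        assert ape[3] == pytest.approx(90.0 - np.degrees(0.3), abs=1e-6)

    def test_backfill_covers_epochs_before_first_setting(self):
        df = epoch_frame([(*STILL, (0, 0, 1)), (*WALK, (0, 0, 1))])
        u, _, _ = track_reference(df, backfill=True)
        np.testing.assert_allclose(u[0], [0, 0, 1])


class TestComputeApe:
    def test_identity_is_zero(self):
        assert compute_ape((0, 0, 1), (0, 0, 1)) == pytest.approx(0.0)

    def test_orthogonal_is_90(self):
        assert compute_ape((1, 0, 0), (0, 0, 1)) == pytest.approx(90.0)

    def test_45_degrees_closed_form(self):
        u = (0, np.sqrt(2) / 2, np.sqrt(2) / 2)
        assert compute_ape((0, 0, 1), u) == pytest.approx(45.0)

    def test_rounding_absorbed_by_clamping(self):
        v = np.array([0.6, 0.8, 0.0])
        v = v / np.linalg.norm(v) * (1 + 1e-12)
        assert compute_ape(v, v) == pytest.approx(0.0)


class TestClassifyPosture:
    @pytest.mark.parametrize(
        "ape,label",
        [
            (8.0, "standing"),
            (11.59, "standing"),
            (11.6, "sitting"),
            (29.99, "sitting"),
            (30.0, "reclining"),
            (45.0, "reclining"),
            (73.89, "reclining"),
            (73.9, "lying"),
            (80.0, "lying"),
        ],
    )
    def test_cutpoints(self, ape, label):
        assert classify_posture(ape) == label

    def test_undefined_ape(self):
        assert classify_posture(float("nan")) == "undefined"

    def test_custom_cutpoints(self):
        c = PostureCutpoints(stand_sit=15.0, sit_recline=40.0, recline_lie=70.0)
        assert classify_posture(12.0, c) == "standing"
        assert classify_posture(45.0, c) == "reclining"


class TestApeHistogram:
    def _annotated(self, apes):
        n = len(apes)
        df = epoch_frame([(*STILL, (0, 0, 1))] * n)
        df["ape_deg"] = apes
        return df

    def test_single_epoch_placement(self):
        hist = build_ape_histogram(self._annotated([3.0]))
        assert hist.loc[0, "minutes"] == pytest.approx(0.1)
        assert hist["minutes"].sum() == pytest.approx(0.1)

    def test_direct_placement(self):
        hist = build_ape_histogram(self._annotated([2.0, 7.0, 87.0]))
        assert hist.loc[0, "minutes"] == pytest.approx(0.1)
        assert hist.loc[1, "minutes"] == pytest.approx(0.1)
        assert hist.loc[17, "minutes"] == pytest.approx(0.1)
        assert hist["minutes"].sum() == pytest.approx(0.3)

    def test_empty_input(self):
        hist = build_ape_histogram(self._annotated([]))
        assert (hist["minutes"] == 0).all()

    def test_structure_18_bins_of_5_degrees(self):
        assert len(APE_BIN_EDGES) - 1 == 18
        widths = np.diff(APE_BIN_EDGES[:-1])
        assert np.all(widths == 5.0)
        assert np.isinf(APE_BIN_EDGES[-1])

    def test_histogram_consistent_with_epoch_labels(self):
        rng = np.random.default_rng(11)
        apes = rng.uniform(0, 90, 400)
        df = self._annotated(apes)
        hist = build_ape_histogram(df)
        labels = classify_posture(apes)
        # standing minutes = bins fully below 10 deg plus the sub-11.6 part of 10-15
        standing_min = (labels == "standing").sum() * 0.1
        bins_below_10 = hist.loc[:1, "minutes"].sum()
        part_10_to_cut = ((apes >= 10) & (apes < 11.6)).sum() * 0.1
        assert standing_min == pytest.approx(bins_below_10 + part_10_to_cut)


class TestScheduleRecovery:
    def test_noise_free_schedule_recovers_postures(self, noise_free_schedule):
        rec, truth = generate_recording(noise_free_schedule, seed=0, sampling_rate=100.0)
        res = run_pipeline(RunConfig(), rec)
        mapping = {
            "standing": "standing",
            "desk_sitting": "sitting",
            "sofa_sitting": "reclining",
            "lying": "lying",
        }
        stationary_truth = truth["activity"].isin(mapping)
        want = truth.loc[stationary_truth, "activity"].map(mapping).to_numpy()
        got = res.epochs.loc[stationary_truth.to_numpy(), "posture"].to_numpy(dtype=object)
        assert (got == want).mean() >= 0.95

    def test_rotation_of_recording_leaves_ape_unchanged(self, noise_free_schedule):
        rec, _ = generate_recording(
            noise_free_schedule, seed=0, sampling_rate=100.0, quantize=False
        )
        rot = Rotation.from_rotvec(np.radians(15) * np.array([1.0, 0.4, 0.2]) / np.linalg.norm([1.0, 0.4, 0.2]))
        rec2 = RawRecording(
            start_time=rec.start_time,
            sampling_rate=rec.sampling_rate,
            samples=rec.samples @ rot.as_matrix().T,
        )
        out = []
        for r in (rec, rec2):
            wear = detect_nonwear(emulate_trigger(r))
            df = compute_epoch_table(r, wear)
            df, _ = annotate_postures(df)
            out.append(df)
        a, b = out
        np.testing.assert_array_equal(a["is_reference"], b["is_reference"])
        assert a["is_reference"].any()
        np.testing.assert_allclose(a["ape_deg"], b["ape_deg"], atol=1e-6)

    def test_conservation_of_stationary_minutes(self, noise_free_schedule):
        rec, _ = generate_recording(noise_free_schedule, seed=1, sampling_rate=100.0)
        res = run_pipeline(RunConfig(), rec)
        hist = build_ape_histogram(res.epochs)
        n_defined = np.isfinite(res.epochs["ape_deg"]).sum()
        assert hist["minutes"].sum() == pytest.approx(n_defined * 0.1)
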