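import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from browkit import features as feat
from browkit import landmarks
from conftest import random_frame, random_series


def make_frame(coords, conf=1.0, frame_index=0):
    """Frame with given {face_id: (x, y)} coords; everything else at origin."""
    face = np.zeros((70, 3))
    face[:, 2] = conf
    for i, (x, y) in coords.items():
        face[i] = (x, y, conf)
    return feat.FrameKeypoints(frame_index=frame_index, face=face)


class TestConfidenceFilter:
    def test_boundary_strictly_below_removed(self, rng):
        series = random_series(rng, 1)
        series.frames[0].face[0, 2] = 0.69
        series.frames[0].face[1, 2] = 0.70
        out = feat.filter_by_confidence(series, 0.7)
        assert math.isnan(out.frames[0].face[0, 0])
        assert not math.isnan(out.frames[0].face[1, 0])

    def test_all_high_confidence_unchanged(self, rng):
        series = random_series(rng, 3)
        for fr in series.frames:
            for part in ("face", "left_hand", "right_hand", "pose"):
                fr.part(part)[:, 2] = 1.0
        out = feat.filter_by_confidence(series, 0.7)
        for fo, fn in zip(series.frames, out.frames):
            np.testing.assert_array_equal(fo.face, fn.face)

    def test_removed_count_matches_brute_force_scan(self, rng):
        series = random_series(rng, 8)
        expected = sum(
            float(c) < 0.7
            for fr in series.frames
            for part in ("face", "left_hand", "right_hand", "pose")
            for c in fr.part(part)[:, 2]
        )
        out = feat.filter_by_confidence(series, 0.7)
        removed = sum(
            int(np.isnan(fr.part(part)[:, 0]).sum())
            for fr in out.frames
            for part in ("face", "left_hand", "right_hand", "pose")
        )
        assert removed == expected

    def test_idempotent(self, rng):
        series = random_series(rng, 5)
        once = feat.filter_by_confidence(series, 0.7)
        twice = feat.filter_by_confidence(once, 0.7)
        for a, b in zip(once.frames, twice.frames):
            np.testing.assert_array_equal(a.face, b.face)

    def test_commutes_with_trim_under_position_independent_dropout(self, rng):
        # confidences drawn i.i.d. of frame position, so filter and trim commute
        series = random_series(rng, 20)
        a = feat.trim_edges(feat.filter_by_confidence(series, 0.7), 0.2)
        b = feat.filter_by_confidence(feat.trim_edges(series, 0.2), 0.7)
        assert len(a) == len(b)
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa.face, fb.face)


class TestNoseRelativeDistance:
    def test_three_four_five_triangle(self):
        frame = make_frame({5: (3.0, 4.0), landmarks.NOSE_TOP: (0.0, 0.0)})
        assert feat.nose_relative_distance(frame, 5, landmarks.NOSE_TOP) == 5.0

    def test_coincident_points_give_zero(self):
        frame = make_frame({5: (7.0, 9.0), landmarks.NOSE_TOP: (7.0, 9.0)})
        assert feat.nose_relative_distance(frame, 5, landmarks.NOSE_TOP) == 0.0

    def test_missing_point_gives_nan(self):
        frame = make_frame({5: (3.0, 4.0), landmarks.NOSE_TOP: (0.0, 0.0)})
        frame.face[5, 2] = 0.0
        assert math.isnan(feat.nose_relative_distance(frame, 5, landmarks.NOSE_TOP))

    def test_matches_two_norm_oracle_on_random_pairs(self, rng):
        for _ in range(1000):
            a, b = rng.uniform(-500, 500, size=(2, 2))
            frame = make_frame({3: tuple(a), landmarks.NOSE_TOP: tuple(b)})
            got = feat.nose_relative_distance(frame, 3, landmarks.NOSE_TOP)
            assert got == pytest.approx(np.linalg.norm(a - b), rel=1e-12)


class TestTrimEdges:
    def test_twenty_percent_of_hundred(self, rng):
        series = random_series(rng, 100)
        out = feat.trim_edges(series, 0.2)
        assert [f.frame_index for f in out.frames] == list(range(20, 80))

    def test_zero_fraction_is_identity(self, rng):
        series = random_series(rng, 37)
        assert len(feat.trim_edges(series, 0.0)) == 37

    @settings(max_examples=60, deadline=None)
    @given(n=st.integers(1, 500), frac=st.floats(0.0, 0.49))
    def test_retained_length_formula(self, n, frac):
        rng = np.random.default_rng(0)
        series = random_series(rng, n)
        assert len(feat.trim_edges(series, frac)) == n - 2 * math.floor(frac * n)


class TestFrameFeatures:
    def brow_frame(self, d21, d22, d18, d25, nose=(0.0, 0.0)):
        coords = {landmarks.NOSE_TOP: nose}
        for i, d in ((21, d21), (22, d22), (18, d18), (25, d25)):
            coords[i] = (nose[0], nose[1] - d)  # straight above the nose
        return make_frame(coords)

    def test_internal_is_mean_of_both_brows(self):
        f = feat.eyebrow_frame_features(self.brow_frame(30.0, 34.0, 50.0, 60.0))
        assert f.internal == pytest.approx(32.0)
        assert f.external == pytest.approx(55.0)

    def test_symmetric_face_has_zero_asymmetry(self):
        frame = make_frame(
            {
                landmarks.NOSE_TOP: (0.0, 0.0),
                21: (-10.0, -30.0), 22: (10.0, -30.0),
                18: (-40.0, -25.0), 25: (40.0, -25.0),
            }
        )
        f = feat.eyebrow_frame_features(frame)
        assert f.asymmetry_internal == pytest.approx(0.0)
        assert f.asymmetry_external == pytest.approx(0.0)

    def test_one_missing_side_blocks_value_when_both_required(self):
        frame = self.brow_frame(30.0, 34.0, 50.0, 60.0)
        frame.face[22, 2] = 0.0  # left inner brow undetected
        f = feat.eyebrow_frame_features(frame)
        assert math.isnan(f.internal)
        assert not math.isnan(f.external)

    def test_interocular_normalization_rescales_by_pupil_distance(self):
        frame = self.brow_frame(30.0, 34.0, 50.0, 60.0)
        frame.face[landmarks.PUPIL_RIGHT, :2] = (-20.0, -10.0)
        frame.face[landmarks.PUPIL_LEFT, :2] = (20.0, -10.0)
        cfg = feat.FeatureConfig(normalize_interocular=True)
        f = feat.eyebrow_frame_features(frame, cfg)
        assert f.internal == pytest.approx(32.0 / 40.0)
        frame.face[landmarks.PUPIL_LEFT, 2] = 0.0  # pupil undetected
        f = feat.eyebrow_frame_features(frame, cfg)
        assert math.isnan(f.internal)

    def test_one_sided_fallback_when_not_required(self):
        frame = self.brow_frame(30.0, 34.0, 50.0, 60.0)
        frame.face[22, 2] = 0.0
        cfg = feat.FeatureConfig(require_both_sides=False)
        f = feat.eyebrow_frame_features(frame, cfg)
        assert f.internal == pytest.approx(30.0)  # surviving right side


class TestSummarizeVideo:
    def series_with_internal(self, rng, values):
        series = random_series(rng, len(values))
        for fr, v in zip(series.frames, values):
            fr.face[:] = 0.0
            fr.face[:, 2] = 1.0
            fr.face[landmarks.NOSE_TOP, :2] = (0.0, 0.0)
            for i in (21, 22):
                fr.face[i, :2] = (0.0, -v)
            for i in (18, 25):
                fr.face[i, :2] = (0.0, -2 * v)
        return series

    def test_mean_of_three_frames(self, rng):
        s = self.series_with_internal(rng, [10.0, 20.0, 30.0])
        vs = feat.summarize_video(s)
        assert vs.mean_internal == pytest.approx(20.0)
        assert vs.n_frames_used_internal == 3

    def test_all_low_confidence_video_is_dropped(self, rng):
        series = random_series(rng, 5)
        for fr in series.frames:
            fr.face[:, 2] = 0.3
        vs = feat.extract_features(series, feat.FeatureConfig(trim_fraction=0.0))
        assert vs.dropped
        assert vs.n_frames_used_internal == 0

    def test_matches_brute_force_mean_oracle(self, rng):
        series = random_series(rng, 30)
        cfg = feat.FeatureConfig()
        filtered = feat.filter_by_confidence(series, cfg.confidence_threshold)
        trimmed = feat.trim_edges(filtered, cfg.trim_fraction)
        vals = [
            feat.eyebrow_frame_features(fr, cfg).internal for fr in trimmed.frames
        ]
        vals = [v for v in vals if not math.isnan(v)]
        vs = feat.extract_features(series, cfg)
        if vals:
            assert vs.mean_internal == pytest.approx(sum(vals) / len(vals))
        else:
            assert math.isnan(vs.mean_internal)

    def test_summary_mean_within_frame_range(self, rng):
        series = self.series_with_internal(rng, list(rng.uniform(10, 60, 20)))
        vs = feat.summarize_video(series)
        vals = [feat.eyebrow_frame_features(fr).internal for fr in series.frames]
        assert min(vals) <= vs.mean_internal <= max(vals)


class TestHandActivityProfile:
    def test_profile_length_equals_frame_count(self, rng):
        series = random_series(rng, 17)
        assert len(feat.hand_activity_profile(series)) == 17

    def test_static_hands_give_constant_profile(self, rng):
        series = random_series(rng, 10)
        for fr in series.frames:
            fr.pose[landmarks.POSE_RIGHT_WRIST] = (100.0, 500.0, 0.9)
            fr.pose[landmarks.POSE_LEFT_WRIST] = (300.0, 500.0, 0.9)
        profile = feat.hand_activity_profile(series)
        np.testing.assert_allclose(profile, 0.0)

    def test_all_missing_hands_give_all_missing_profile(self, rng):
        series = random_series(rng, 6)
        for fr in series.frames:
            fr.pose[:, 2] = 0.0
        assert np.isnan(feat.hand_activity_profile(series)).all()

    def test_ramps_confined_to_edges_on_synthetic_video(self, rng):
        # wrists rest low in the first/last 20% and are raised in between
        n, k = 30, 6
        series = random_series(rng, n)
        for i, fr in enumerate(series.frames):
            y = 650.0 if (i < k or i >= n - k) else 400.0
            fr.pose[landmarks.POSE_RIGHT_WRIST] = (100.0, y, 0.9)
            fr.pose[landmarks.POSE_LEFT_WRIST] = (300.0, y, 0.9)
        profile = feat.hand_activity_profile(series)
        assert (profile[:k] == 0.0).all() and (profile[n - k:] == 0.0).all()
        assert (profile[k : n - k] > 200.0).all()


class TestFeatureConfig:
    def test_overlapping_landmark_ids_rejected(self):
        with pytest.raises(ValueError):
            feat.FeatureConfig(internal_ids=(21, 27))

    @pytest.mark.parametrize("kwargs", [
        {"confidence_threshold": 1.2}, {"trim_fraction": 0.5}, {"trim_fraction": -0.1},
    ])
    def test_out_of_range_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            feat.FeatureConfig(**kwargs)
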