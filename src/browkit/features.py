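"""Per-video eyebrow-position features from keypoint time series.

Raw y-coordinates confound eyebrow movement with camera placement, body
height and head motion, so eyebrow position is measured as the Euclidean
distance between each eyebrow landmark and the top of the nose bridge —
a head-relative quantity.  The pipeline per video is:

1. drop keypoints whose detection confidence falls below a threshold,
2. trim a fixed fraction of frames from each end of the video (hand
   raise/lower preparation and retraction),
3. compute per-frame internal/external eyebrow distances, averaging the
   two brows,
4. average over frames to one summary row per video — the modelling unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from . import landmarks
from .keypoints_io import FrameKeypoints, KeypointTimeSeries, VideoMetadata, copy_series


@dataclass(frozen=True)
class FeatureConfig:
    """Constants of the feature-extraction stage.

    confidence_threshold
        Keypoints with confidence strictly below this are discarded;
        equality keeps the point.
    trim_fraction
        Fraction of frames removed from each end of the video (positional,
        ``floor(fraction * n)`` per end).
    require_both_sides
        If true, a frame contributes an internal (external) value only when
        both the left and right constituent landmarks survive filtering;
        one-sided dropout would otherwise bias means given brow asymmetry.
    normalize_interocular
        If true, distances are divided by the frame's pupil-to-pupil
        distance instead of being reported in raw pixels.  Off by default:
        with a fixed camera and a seated signer, raw pixels are already
        comparable within signer, and normalization would rescale the
        effect estimates away from the pixel units reported downstream.
    """

    confidence_threshold: float = 0.7
    trim_fraction: float = 0.2
    internal_ids: tuple[int, int] = landmarks.INTERNAL_IDS
    external_ids: tuple[int, int] = landmarks.EXTERNAL_IDS
    nose_id: int = landmarks.NOSE_TOP
    require_both_sides: bool = True
    normalize_interocular: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must lie in [0, 1]")
        if not 0.0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must lie in [0, 0.5)")
        ids = set(self.internal_ids) | set(self.external_ids) | {self.nose_id}
        if len(ids) != len(self.internal_ids) + len(self.external_ids) + 1:
            raise ValueError("internal/external/nose landmark ids must be disjoint")
        if any(i >= landmarks.N_FACE_POINTS or i < 0 for i in ids):
            raise ValueError("landmark ids must be valid 70-point face indices")


@dataclass
class EyebrowFrameFeatures:
    """Nose-relative eyebrow distances of one frame (NaN = missing)."""

    frame_index: int
    d_internal_left: float = math.nan
    d_internal_right: float = math.nan
    d_external_left: float = math.nan
    d_external_right: float = math.nan
    internal: float = math.nan
    external: float = math.nan
    asymmetry_internal: float = math.nan  # left minus right
    asymmetry_external: float = math.nan


@dataclass
class VideoSummary:
    """Per-video mean eyebrow position — one row of the modelling table."""

    metadata: VideoMetadata
    mean_internal: float
    mean_external: float
    n_frames_total: int
    n_frames_used_internal: int
    n_frames_used_external: int

    @property
    def dropped(self) -> bool:
        return math.isnan(self.mean_internal) and math.isnan(self.mean_external)


def filter_by_confidence(
    series: KeypointTimeSeries, threshold: float = 0.7
) -> KeypointTimeSeries:
    """Mark keypoints with confidence strictly below ``threshold`` missing.

    Missing points get NaN coordinates and confidence 0.  Idempotent:
    already-missing points (confidence 0 < threshold) stay missing.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    out = copy_series(series)
    for fr in out.frames:
        for part in ("face", "left_hand", "right_hand", "pose"):
            pts = fr.part(part)
            if pts.size == 0:
                continue
            low = pts[:, 2] < threshold
            pts[low, 0] = np.nan
            pts[low, 1] = np.nan
            pts[low, 2] = 0.0
    return out


def trim_edges(series: KeypointTimeSeries, fraction: float = 0.2) -> KeypointTimeSeries:
    """Drop the first and last ``floor(fraction * n)`` frames (by position)."""
    if not 0.0 <= fraction < 0.5:
        raise ValueError("fraction must lie in [0, 0.5)")
    n = len(series.frames)
    k = int(math.floor(fraction * n))
    return replace(series, frames=series.frames[k : n - k])


def nose_relative_distance(frame: FrameKeypoints, face_id: int, nose_id: int) -> float:
    """Euclidean distance (pixels) from a face landmark to the nose landmark.

    NaN when either point is missing (NaN coordinates or confidence 0).
    """
    face = frame.face
    if len(face) <= max(face_id, nose_id):
        return math.nan
    b, n = face[face_id], face[nose_id]
    if b[2] == 0.0 or n[2] == 0.0:
        return math.nan
    return float(math.hypot(b[0] - n[0], b[1] - n[1]))


def hand_activity_profile(series: KeypointTimeSeries) -> np.ndarray:
    """Per-frame hand elevation above the video's resting wrist height.

    Mean wrist height (pixels above the lowest observed wrist position;
    image y grows downward, so elevation = baseline_y - wrist_y) averaged
    over the detected wrists.  A diagnostic used to inspect how much of a
    video's edges is occupied by hand raising/lowering; the trim fraction
    itself is a fixed configuration constant, not auto-detected.
    """
    heights = np.full(len(series.frames), np.nan)
    ys = []
    for i, fr in enumerate(series.frames):
        pose = fr.pose
        vals = []
        for wrist in (landmarks.POSE_RIGHT_WRIST, landmarks.POSE_LEFT_WRIST):
            if len(pose) > wrist and pose[wrist, 2] > 0 and not math.isnan(pose[wrist, 1]):
                vals.append(pose[wrist, 1])
        if vals:
            heights[i] = np.mean(vals)
        ys.extend(vals)
    if not ys:
        return heights  # all missing
    baseline = max(ys)  # largest y = lowest (resting) wrist position
    return baseline - heights


def _pair_mean(left: float, right: float, require_both: bool) -> float:
    have_l, have_r = not math.isnan(left), not math.isnan(right)
    if have_l and have_r:
        return (left + right) / 2.0
    if require_both or not (have_l or have_r):
        return math.nan
    return left if have_l else right


def eyebrow_frame_features(
    frame: FrameKeypoints, config: FeatureConfig = FeatureConfig()
) -> EyebrowFrameFeatures:
    """Internal/external eyebrow distances for one frame.

    internal = mean of the two inner-brow distances, external = mean of the
    two outer-brow distances; asymmetry = left minus right distance, defined
    only when both sides are present.
    """
    right_in, left_in = config.internal_ids
    right_ex, left_ex = config.external_ids
    d_il = nose_relative_distance(frame, left_in, config.nose_id)
    d_ir = nose_relative_distance(frame, right_in, config.nose_id)
    d_el = nose_relative_distance(frame, left_ex, config.nose_id)
    d_er = nose_relative_distance(frame, right_ex, config.nose_id)
    if config.normalize_interocular:
        face = frame.face
        scale = math.nan
        if len(face) > max(landmarks.PUPIL_RIGHT, landmarks.PUPIL_LEFT):
            a, b = face[landmarks.PUPIL_RIGHT], face[landmarks.PUPIL_LEFT]
            if a[2] > 0 and b[2] > 0:
                scale = math.hypot(a[0] - b[0], a[1] - b[1])
        d_il, d_ir, d_el, d_er = (d / scale for d in (d_il, d_ir, d_el, d_er))
    return EyebrowFrameFeatures(
        frame_index=frame.frame_index,
        d_internal_left=d_il,
        d_internal_right=d_ir,
        d_external_left=d_el,
        d_external_right=d_er,
        internal=_pair_mean(d_il, d_ir, config.require_both_sides),
        external=_pair_mean(d_el, d_er, config.require_both_sides),
        asymmetry_internal=d_il - d_ir,
        asymmetry_external=d_el - d_er,
    )


def summarize_video(
    series: KeypointTimeSeries, config: FeatureConfig = FeatureConfig()
) -> VideoSummary:
    """Average per-frame eyebrow features into one summary row.

    Expects filtering and trimming to have been applied already (see
    :func:`extract_features` for the full pipeline).  A variable with no
    valid frame is NaN; a video with both variables NaN is dropped from
    modelling.
    """
    feats = [eyebrow_frame_features(fr, config) for fr in series.frames]
    internal = np.array([f.internal for f in feats])
    external = np.array([f.external for f in feats])
    n_int = int(np.sum(~np.isnan(internal)))
    n_ext = int(np.sum(~np.isnan(external)))
    return VideoSummary(
        metadata=series.metadata,
        mean_internal=float(np.nanmean(internal)) if n_int else math.nan,
        mean_external=float(np.nanmean(external)) if n_ext else math.nan,
        n_frames_total=len(series.frames),
        n_frames_used_internal=n_int,
        n_frames_used_external=n_ext,
    )


def extract_features(
    series: KeypointTimeSeries, config: FeatureConfig = FeatureConfig()
) -> VideoSummary:
    """Full per-video pipeline: filter -> trim -> frame features -> mean."""
    filtered = filter_by_confidence(series, config.confidence_threshold)
    trimmed = trim_edges(filtered, config.trim_fraction)
    return summarize_video(trimmed, config)


def summary_table(summaries: Iterable[VideoSummary]) -> pd.DataFrame:
    """Per-video feature table (one row per video, CSV-ready)."""
    rows = []
    for s in summaries:
        md = s.metadata
        rows.append(
            {
                "video_id": md.video_id,
                "signer_id": md.signer_id,
                "group": md.group,
                "sentence_id": md.sentence_id,
                "emotion": md.emotion,
                "sentence_type": md.sentence_type,
                "mean_internal": s.mean_internal,
                "mean_external": s.mean_external,
                "n_frames_total": s.n_frames_total,
                "n_frames_used_internal": s.n_frames_used_internal,
                "n_frames_used_external": s.n_frames_used_external,
                "dropped": s.dropped,
            }
        )
    return pd.DataFrame(rows)
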