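"""Reading and writing OpenPose keypoint data.

OpenPose writes one JSON document per video frame with a top-level
``"people"`` array; each person carries flat ``[x1, y1, c1, x2, y2, c2, ...]``
arrays for the 70-point face, the two 21-point hands and the body pose.
This module parses those documents into typed frame/series containers and
round-trips whole collections through a single flat CSV table (one row per
keypoint) for archival and inspection.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import landmarks

logger = logging.getLogger(__name__)

GROUPS = ("deaf", "hearing")
EMOTIONS = ("neutral", "anger", "surprise")
SENTENCE_TYPES = ("statement", "polar", "wh")

#: parts of the body tracked per frame, in combined-table order
PARTS = ("face", "left_hand", "right_hand", "pose")

_PART_JSON_KEYS = {
    "face": "face_keypoints_2d",
    "left_hand": "hand_left_keypoints_2d",
    "right_hand": "hand_right_keypoints_2d",
    "pose": "pose_keypoints_2d",
}

#: decimal places kept in the combined table; sub-pixel beyond this is noise
TABLE_PRECISION = 6

_FRAME_INDEX_RE = re.compile(r"(\d+)_keypoints\.json$")


class FormatError(ValueError):
    """A keypoint document or table does not follow the expected schema."""


@dataclass(frozen=True)
class VideoMetadata:
    """Identity and experimental condition of one recorded video."""

    video_id: str
    signer_id: str
    group: str
    sentence_id: str
    emotion: str
    sentence_type: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion {self.emotion!r}; expected one of {EMOTIONS}")
        if self.sentence_type not in SENTENCE_TYPES:
            raise ValueError(
                f"unknown sentence_type {self.sentence_type!r}; expected one of {SENTENCE_TYPES}"
            )


@dataclass
class FrameKeypoints:
    """One frame's detected keypoints.

    Each part is an ``(n, 3)`` float array of ``(x, y, confidence)`` rows.
    A confidence of exactly 0 marks an undetected point (OpenPose's own
    convention); NaN coordinates mark points removed by filtering.
    """

    frame_index: int
    face: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    left_hand: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    right_hand: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    pose: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    person_present: bool = True

    def part(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass
class KeypointTimeSeries:
    """Ordered frames of one video plus its metadata."""

    metadata: VideoMetadata
    frames: list[FrameKeypoints]
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


def _unflatten(flat: Sequence[float], part: str, source: str) -> np.ndarray:
    arr = np.asarray(flat, dtype=float)
    if arr.size % 3 != 0:
        raise FormatError(
            f"{source}: {_PART_JSON_KEYS[part]} length {arr.size} is not a multiple of 3"
        )
    pts = arr.reshape(-1, 3)
    n = len(pts)
    if part == "face" and n != landmarks.N_FACE_POINTS:
        raise FormatError(
            f"{source}: face_keypoints_2d has {n} points, expected {landmarks.N_FACE_POINTS}"
        )
    if part in ("left_hand", "right_hand") and n not in (0, landmarks.N_HAND_POINTS):
        raise FormatError(
            f"{source}: {_PART_JSON_KEYS[part]} has {n} points, "
            f"expected {landmarks.N_HAND_POINTS}"
        )
    # pose length is deliberately lax: both 25- and 24-point exports occur
    return pts


def read_openpose_frame(
    document: str | bytes | dict, frame_index: int = 0, source: str = "<document>"
) -> FrameKeypoints:
    """Parse one OpenPose per-frame JSON document.

    An empty ``"people"`` array yields ``person_present=False`` with empty
    parts.  When several people were detected the first is used (recordings
    contain a single signer by design) and a warning is logged.
    """
    if isinstance(document, (str, bytes)):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{source}: not valid JSON ({exc})") from exc
    if not isinstance(document, dict) or "people" not in document:
        raise FormatError(f"{source}: missing top-level 'people' array")
    people = document["people"]
    if not people:
        return FrameKeypoints(frame_index=frame_index, person_present=False)
    if len(people) > 1:
        logger.warning("%s: %d people detected, using the first", source, len(people))
    person = people[0]
    parts = {}
    for part, key in _PART_JSON_KEYS.items():
        parts[part] = _unflatten(person.get(key, []), part, source)
    return FrameKeypoints(frame_index=frame_index, person_present=True, **parts)


def write_openpose_frame(frame: FrameKeypoints, precision: int = TABLE_PRECISION) -> str:
    """Serialize a frame back to the OpenPose JSON dialect."""
    if not frame.person_present:
        return json.dumps({"version": 1.5, "people": []})
    person = {}
    for part, key in _PART_JSON_KEYS.items():
        arr = np.round(frame.part(part), precision)
        person[key] = [float(v) for v in arr.ravel()]
    return json.dumps({"version": 1.5, "people": [person]})


def parse_frame_index(filename: str) -> int | None:
    """Extract the frame index from an OpenPose-style file name.

    OpenPose emits ``<prefix>_%012d_keypoints.json``; any name with a final
    integer group before ``_keypoints.json`` is accepted.
    """
    m = _FRAME_INDEX_RE.search(filename)
    return int(m.group(1)) if m else None


def load_video(directory: str | Path, metadata: VideoMetadata, fps: float = 30.0) -> KeypointTimeSeries:
    """Load all per-frame documents of one video, sorted by frame index.

    Unreadable files are skipped with a logged warning; gaps in the index
    sequence are permitted.  Raises :class:`FormatError` if no frame can be
    parsed.
    """
    directory = Path(directory)
    entries = []
    for path in sorted(directory.glob("*_keypoints.json")):
        idx = parse_frame_index(path.name)
        if idx is None:
            continue
        entries.append((idx, path))
    entries.sort(key=lambda e: e[0])
    frames = []
    for idx, path in entries:
        try:
            frames.append(read_openpose_frame(path.read_text(), idx, source=str(path)))
        except FormatError as exc:
            logger.warning("skipping unreadable frame file: %s", exc)
    if not frames:
        raise FormatError(f"{directory}: no parseable *_keypoints.json frame files")
    return KeypointTimeSeries(metadata=metadata, frames=frames, fps=fps)


_META_COLUMNS = ["signer_id", "group", "sentence_id", "emotion", "sentence_type"]
TABLE_COLUMNS = (
    ["video_id"] + _META_COLUMNS + ["frame_index", "part", "point_index", "x", "y", "confidence"]
)


def combined_table(collection: Iterable[KeypointTimeSeries]) -> pd.DataFrame:
    """Flatten a collection of series into one row-per-keypoint table."""
    records = []
    for series in collection:
        md = series.metadata
        meta = (md.video_id, md.signer_id, md.group, md.sentence_id, md.emotion, md.sentence_type)
        for fr in series.frames:
            for part in PARTS:
                pts = fr.part(part)
                for j in range(len(pts)):
                    records.append(meta + (fr.frame_index, part, j) + tuple(pts[j]))
    df = pd.DataFrame(records, columns=TABLE_COLUMNS)
    df[["x", "y", "confidence"]] = df[["x", "y", "confidence"]].round(TABLE_PRECISION)
    return df


def write_combined_table(collection: Iterable[KeypointTimeSeries], path: str | Path) -> None:
    """Write the flat keypoint table as UTF-8 CSV ('.' decimal separator)."""
    combined_table(collection).to_csv(path, index=False)


def read_combined_table(path: str | Path) -> list[KeypointTimeSeries]:
    """Read a combined table back into a list of series (inverse of write)."""
    df = pd.read_csv(path, dtype={"sentence_id": str})
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: combined table missing columns {missing}")
    out = []
    for video_id, vdf in df.groupby("video_id", sort=False):
        first = vdf.iloc[0]
        md = VideoMetadata(
            video_id=str(video_id),
            signer_id=str(first["signer_id"]),
            group=str(first["group"]),
            sentence_id=str(first["sentence_id"]),
            emotion=str(first["emotion"]),
            sentence_type=str(first["sentence_type"]),
        )
        frames = []
        for frame_index, fdf in vdf.groupby("frame_index", sort=True):
            parts = {}
            for part in PARTS:
                pdf = fdf[fdf["part"] == part].sort_values("point_index")
                parts[part] = pdf[["x", "y", "confidence"]].to_numpy(dtype=float)
            frames.append(FrameKeypoints(frame_index=int(frame_index), **parts))
        out.append(KeypointTimeSeries(metadata=md, frames=frames))
    return out


def copy_series(series: KeypointTimeSeries) -> KeypointTimeSeries:
    """Deep copy (frames are copied arrays; metadata is shared, immutable)."""
    frames = [
        FrameKeypoints(
            frame_index=f.frame_index,
            face=f.face.copy(),
            left_hand=f.left_hand.copy(),
            right_hand=f.right_hand.copy(),
            pose=f.pose.copy(),
            person_present=f.person_present,
        )
        for f in series.frames
    ]
    return replace(series, frames=frames)
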