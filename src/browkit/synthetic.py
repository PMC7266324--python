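"""Synthetic keypoint study generator with exact ground truth.

Generates datasets with the structure the analysis assumes — a full
signer x sentence x emotion x sentence-type design, condition effects
injected in contrast space, by-signer and by-sentence random intercepts and
slopes, per-frame noise, confidence dropouts, and hand raise/lower ramps at
the video edges — either as a per-video summary table (fast, for model
simulations) or as complete OpenPose per-frame JSON documents on disk
(for end-to-end pipeline runs).

Effects are mapped to condition-cell means through the same contrast coding
the model uses, so every injected coefficient is a well-defined recovery
target.  Eyebrow landmarks are placed at ``nose + unit_direction * distance``
so the nose-relative distance the pipeline measures equals the injected
value by construction.

Geometry: a 1280x720 canvas, face centred high, image y grows downward, so
an eyebrow raise is a larger nose distance.  Default effect sizes are the
study-scale estimates this package is built around (pixels); frame- and
group-level noise magnitudes are free parameters chosen to give contrast
standard errors of the order observed at that scale, and are documented as
such.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import landmarks
from .keypoints_io import EMOTIONS, GROUPS, SENTENCE_TYPES, VideoMetadata
from .mixed_model import RANDOM_STRUCTURE, ContrastScheme, build_design

#: default injected fixed effects, pixels, keyed by design column
EFFECTS_INTERNAL = {
    "emotion_c1": 3.7,   # neutral - anger
    "emotion_c2": 4.0,   # surprise - mean(neutral, anger)
    "stype_c1": 0.3,     # wh - statement
    "stype_c2": 2.3,     # polar - mean(statement, wh)
    "stype_c2:group_c1": -1.8,  # polar raise attenuated for deaf signers
}
EFFECTS_EXTERNAL = {
    "emotion_c1": 0.45,
    "emotion_c2": 2.5,
    "stype_c1": 0.09,
    "stype_c2": 2.5,
    "stype_c1:group_c1": -1.8,
    "stype_c2:group_c1": -2.3,
    "emotion_c2:stype_c1": -2.0,  # wh-vs-statement raise counteracted by surprise
    "emotion_c2:stype_c1:group_c1": -3.3,
}

#: pixels added to eyebrow distances outside the central span, so that
#: trimming the video edges measurably matters
EDGE_PERTURBATION = 6.0

_CANVAS = (1280, 720)
_NOSE_XY = (640.0, 250.0)
# unit directions from the nose top to the four eyebrow landmarks
_BROW_ANGLES = {  # degrees from vertical; negative x = subject's right side
    landmarks.INTERNAL_RIGHT: -32.0,
    landmarks.INTERNAL_LEFT: 32.0,
    landmarks.EXTERNAL_RIGHT: -55.0,
    landmarks.EXTERNAL_LEFT: 55.0,
}
_WRIST_REST_Y = 650.0
_WRIST_RAISED_Y = 400.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study design and noise structure of the generated data.

    Counts default to the study design (5 deaf + 4 hearing signers, 10
    sentences, 3 emotions x 3 sentence types, one 3-second video at 30 fps
    per cell = 810 videos, of which ``n_voided`` contain no usable frames).
    """

    n_signers_deaf: int = 5
    n_signers_hearing: int = 4
    n_sentences: int = 10
    frames_per_video: int = 90
    fps: float = 30.0
    baseline_internal: float = 45.0
    baseline_external: float = 75.0
    effects_internal: dict = field(default_factory=lambda: dict(EFFECTS_INTERNAL))
    effects_external: dict = field(default_factory=lambda: dict(EFFECTS_EXTERNAL))
    sd_signer: float = 2.0          # by-signer random intercept, px
    sd_sentence: float = 1.5        # by-sentence random intercept, px
    sd_signer_slope: float = 1.2    # by-signer random slopes, px
    sd_sentence_slope: float = 0.8  # by-sentence random slopes, px
    sd_frame: float = 3.0           # frame-level noise on each variable, px
    p_lowconf: float = 0.08         # per-keypoint chance of confidence < 0.7
    hand_ramp_fraction: float = 0.2
    trim_fraction: float = 0.2      # used to size summary-level residual noise
    n_voided: int = 5               # videos rendered with no usable keypoints
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_signers_deaf + self.n_signers_hearing, self.n_sentences,
               self.frames_per_video) < 1:
            raise ValueError("counts must be >= 1")
        for sd in (self.sd_signer, self.sd_sentence, self.sd_signer_slope,
                   self.sd_sentence_slope, self.sd_frame):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.p_lowconf <= 1.0:
            raise ValueError("p_lowconf must lie in [0, 1]")

    @property
    def n_videos(self) -> int:
        return (
            (self.n_signers_deaf + self.n_signers_hearing)
            * self.n_sentences
            * len(EMOTIONS)
            * len(SENTENCE_TYPES)
        )

    @property
    def signers(self) -> list[tuple[str, str]]:
        deaf = [(f"D{i + 1}", "deaf") for i in range(self.n_signers_deaf)]
        hearing = [(f"H{i + 1}", "hearing") for i in range(self.n_signers_hearing)]
        return deaf + hearing

    @property
    def n_frames_retained(self) -> int:
        """Frames surviving the positional edge trim."""
        k = int(math.floor(self.trim_fraction * self.frames_per_video))
        return self.frames_per_video - 2 * k


@dataclass
class GroundTruth:
    """Everything needed to predict each video's noise-free summary."""

    config: SyntheticConfig
    videos: pd.DataFrame  # video_id + metadata + mu_internal, mu_external
    signer_effects: dict[str, dict[str, dict[str, float]]]  # outcome -> signer -> col -> px
    sentence_effects: dict[str, dict[str, dict[str, float]]]
    voided: list[str]

    def expected_summary(self, video_id: str, outcome: str) -> float:
        """Exact per-video mean under zero frame noise (NaN if voided)."""
        if video_id in self.voided:
            return math.nan
        row = self.videos.set_index("video_id").loc[video_id]
        return float(row[f"mu_{outcome}"])

    def fixed_cell_mean(self, emotion: str, sentence_type: str, group: str,
                        outcome: str) -> float:
        """Population cell mean: baseline + contrast-mapped fixed effects."""
        cell = pd.DataFrame(
            {"emotion": [emotion], "sentence_type": [sentence_type], "group": [group]}
        )
        X = build_design(cell)
        base = (self.config.baseline_internal if outcome == "internal"
                else self.config.baseline_external)
        effects = (self.config.effects_internal if outcome == "internal"
                   else self.config.effects_external)
        return base + float(sum(X.iloc[0][c] * v for c, v in effects.items()))


def design_table(config: SyntheticConfig) -> pd.DataFrame:
    """The full video grid: one row per signer x sentence x emotion x type."""
    rows = []
    for signer_id, group in config.signers:
        for s in range(1, config.n_sentences + 1):
            sentence_id = f"sent{s:02d}"
            for emotion in EMOTIONS:
                for stype in SENTENCE_TYPES:
                    rows.append(
                        {
                            "video_id": f"{signer_id}_{sentence_id}_{emotion}_{stype}",
                            "signer_id": signer_id,
                            "group": group,
                            "sentence_id": sentence_id,
                            "emotion": emotion,
                            "sentence_type": stype,
                        }
                    )
    return pd.DataFrame(rows)


def _draw_random_effects(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[dict, dict]:
    """Per-outcome random intercepts/slopes for signers and sentences."""
    signer_effects: dict = {}
    sentence_effects: dict = {}
    sentences = [f"sent{s:02d}" for s in range(1, config.n_sentences + 1)]
    for outcome in ("internal", "external"):
        signer_effects[outcome] = {}
        for signer_id, _ in config.signers:
            eff = {}
            for col in RANDOM_STRUCTURE["signer_id"]:
                sd = config.sd_signer if col == "Intercept" else config.sd_signer_slope
                eff[col] = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
            signer_effects[outcome][signer_id] = eff
        sentence_effects[outcome] = {}
        for sentence_id in sentences:
            eff = {}
            for col in RANDOM_STRUCTURE["sentence_id"]:
                sd = config.sd_sentence if col == "Intercept" else config.sd_sentence_slope
                eff[col] = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
            sentence_effects[outcome][sentence_id] = eff
    return signer_effects, sentence_effects


def ground_truth(config: SyntheticConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw the latent structure: video grid, random effects, voided set."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    videos = design_table(config)
    X = build_design(videos)
    signer_effects, sentence_effects = _draw_random_effects(config, rng)
    for outcome, base, effects in (
        ("internal", config.baseline_internal, config.effects_internal),
        ("external", config.baseline_external, config.effects_external),
    ):
        mu = np.full(len(videos), base)
        for col, v in effects.items():
            mu += v * X[col].to_numpy()
        for i, row in videos.iterrows():
            se = signer_effects[outcome][row["signer_id"]]
            te = sentence_effects[outcome][row["sentence_id"]]
            mu[i] += sum(se[c] * X.at[i, c] for c in se)
            mu[i] += sum(te[c] * X.at[i, c] for c in te)
        videos[f"mu_{outcome}"] = mu
    if config.n_voided > len(videos):
        raise ValueError("n_voided exceeds the number of videos")
    voided = sorted(
        rng.choice(videos["video_id"].to_numpy(), size=config.n_voided, replace=False)
    ) if config.n_voided else []
    return GroundTruth(
        config=config,
        videos=videos,
        signer_effects=signer_effects,
        sentence_effects=sentence_effects,
        voided=list(voided),
    )


def simulate_summary_table(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-video summary table drawn directly at the modelling level.

    Observed means are the ground-truth expectations plus residual noise of
    magnitude ``sd_frame / sqrt(n_frames_retained)`` — the noise the full
    pipeline would leave after averaging the retained frames.  Voided videos
    get missing outcomes.  Fast path for parameter-recovery and
    type-I-error simulations that do not need keypoint files.
    """
    config = config or SyntheticConfig()
    if seed is not None:
        config = SyntheticConfig(**{**config.__dict__, "seed": seed})
    rng = np.random.default_rng(config.seed)
    gt = ground_truth(config, rng)
    df = gt.videos.copy()
    resid_sd = config.sd_frame / math.sqrt(max(config.n_frames_retained, 1))
    for outcome in ("internal", "external"):
        noise = rng.normal(0.0, resid_sd, size=len(df)) if resid_sd > 0 else 0.0
        df[f"mean_{outcome}"] = df[f"mu_{outcome}"] + noise
    df["n_frames_total"] = config.n_frames_retained
    df["n_frames_used_internal"] = config.n_frames_retained
    df["n_frames_used_external"] = config.n_frames_retained
    void = df["video_id"].isin(gt.voided)
    df.loc[void, ["mean_internal", "mean_external"]] = np.nan
    df.loc[void, ["n_frames_used_internal", "n_frames_used_external"]] = 0
    df["dropped"] = void
    return df.drop(columns=["mu_internal", "mu_external"]), gt


def _face_template() -> np.ndarray:
    """Fixed 70-point face scaffold (x, y); only 5 indices carry signal."""
    pts = np.zeros((landmarks.N_FACE_POINTS, 2))
    cx, cy = _NOSE_XY[0], _NOSE_XY[1] + 60.0
    for i in range(landmarks.N_FACE_POINTS):
        ang = 2.0 * math.pi * i / landmarks.N_FACE_POINTS
        pts[i] = (cx + 90.0 * math.cos(ang), cy + 110.0 * math.sin(ang))
    pts[landmarks.NOSE_TOP] = _NOSE_XY
    return pts


def _brow_position(brow_id: int, distance: float) -> tuple[float, float]:
    ang = math.radians(_BROW_ANGLES[brow_id])
    ux, uy = math.sin(ang), -math.cos(ang)  # y decreases upward
    return (_NOSE_XY[0] + ux * distance, _NOSE_XY[1] + uy * distance)


def _wrist_y(i: int, n: int, ramp_k: int) -> float:
    if ramp_k == 0:
        return _WRIST_RAISED_Y
    if i < ramp_k:
        frac = i / ramp_k
    elif i >= n - ramp_k:
        frac = (n - 1 - i) / ramp_k
    else:
        frac = 1.0
    return _WRIST_REST_Y + frac * (_WRIST_RAISED_Y - _WRIST_REST_Y)


def _confidences(
    n: int, rng: np.random.Generator, p_lowconf: float, voided: bool
) -> np.ndarray:
    if voided:
        return rng.uniform(0.1, 0.5, size=n)
    conf = rng.uniform(0.85, 1.0, size=n)
    low = rng.random(n) < p_lowconf
    conf[low] = rng.uniform(0.2, 0.65, size=int(low.sum()))
    return conf


def generate_study(
    config: SyntheticConfig | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Write a full synthetic study as OpenPose per-frame JSON files.

    Creates ``out_dir/<video_id>/<video_id>_<frame:012d>_keypoints.json``
    plus ``out_dir/metadata.csv``.  Deterministic given the seed (byte
    identical).  Returns the metadata table and the ground truth.

    Per frame, both eyebrows' internal (external) distances equal the
    video's ground-truth mean plus one shared Gaussian draw, with a fixed
    upward perturbation outside the central span so that edge trimming has
    a measurable effect; wrists ramp up/down over the edge spans.
    """
    config = config or SyntheticConfig()
    if seed is not None:
        config = SyntheticConfig(**{**config.__dict__, "seed": seed})
    if out_dir is None:
        raise ValueError("out_dir is required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    gt = ground_truth(config, rng)
    template = _face_template()
    n = config.frames_per_video
    ramp_k = int(math.floor(config.hand_ramp_fraction * n))
    voided_set = set(gt.voided)

    for _, video in gt.videos.iterrows():
        vid = video["video_id"]
        vdir = out_dir / vid
        vdir.mkdir(exist_ok=True)
        is_void = vid in voided_set
        noise_int = rng.normal(0.0, config.sd_frame, size=n) if config.sd_frame else np.zeros(n)
        noise_ext = rng.normal(0.0, config.sd_frame, size=n) if config.sd_frame else np.zeros(n)
        for i in range(n):
            edge = EDGE_PERTURBATION if (i < ramp_k or i >= n - ramp_k) else 0.0
            d_int = video["mu_internal"] + noise_int[i] + edge
            d_ext = video["mu_external"] + noise_ext[i] + edge
            face = template.copy()
            for bid in landmarks.INTERNAL_IDS:
                face[bid] = _brow_position(bid, d_int)
            for bid in landmarks.EXTERNAL_IDS:
                face[bid] = _brow_position(bid, d_ext)
            conf = _confidences(landmarks.N_FACE_POINTS, rng, config.p_lowconf, is_void)
            face_flat = np.column_stack([face, conf]).ravel()

            wy = _wrist_y(i, n, ramp_k)
            pose = np.zeros((25, 3))
            pose[:, 0] = _NOSE_XY[0]
            pose[:, 1] = 400.0
            pose[:, 2] = 0.9
            pose[landmarks.POSE_RIGHT_WRIST] = (_NOSE_XY[0] - 200.0, wy, 0.9)
            pose[landmarks.POSE_LEFT_WRIST] = (_NOSE_XY[0] + 200.0, wy, 0.9)
            hands = {
                "hand_left_keypoints_2d": _hand_flat(_NOSE_XY[0] + 200.0, wy),
                "hand_right_keypoints_2d": _hand_flat(_NOSE_XY[0] - 200.0, wy),
            }
            doc = {
                "version": 1.5,
                "people": [
                    {
                        "face_keypoints_2d": [round(float(v), 6) for v in face_flat],
                        "pose_keypoints_2d": [round(float(v), 6) for v in pose.ravel()],
                        **hands,
                    }
                ],
            }
            path = vdir / f"{vid}_{i:012d}_keypoints.json"
            path.write_text(json.dumps(doc))

    meta = gt.videos.drop(columns=["mu_internal", "mu_external"])
    meta.to_csv(out_dir / "metadata.csv", index=False)
    gt_path = out_dir / "ground_truth.json"
    gt_path.write_text(
        json.dumps(
            {
                "voided": gt.voided,
                "mu_internal": dict(zip(gt.videos["video_id"], gt.videos["mu_internal"])),
                "mu_external": dict(zip(gt.videos["video_id"], gt.videos["mu_external"])),
            }
        )
    )
    return meta, gt


def _hand_flat(cx: float, cy: float) -> list[float]:
    pts = []
    for j in range(landmarks.N_HAND_POINTS):
        pts.extend([round(cx + 2.0 * j, 6), round(cy + 1.0 * j, 6), 0.9])
    return pts


def metadata_from_row(row: pd.Series) -> VideoMetadata:
    return VideoMetadata(
        video_id=str(row["video_id"]),
        signer_id=str(row["signer_id"]),
        group=str(row["group"]),
        sentence_id=str(row["sentence_id"]),
        emotion=str(row["emotion"]),
        sentence_type=str(row["sentence_type"]),
    )


# ---------------------------------------------------------------------------
# rating-table generator for the validation statistics

RATING_EMOTION_MAP = {"neutral": "neutral", "anger": "angry", "surprise": "surprised"}

#: per-sentence-type probability of choosing the intended label
DEFAULT_CORRECTNESS = {"statement": 0.73, "polar": 0.58, "wh": 0.56}


def default_confusion(
    correctness: dict[str, float] | None = None, p_other: float = 0.2
) -> dict:
    """Confusion distributions keyed by (intended, sentence_type).

    The intended label gets the stratum's correctness probability; of the
    error mass, ``p_other`` goes to "other" and the rest splits evenly over
    the two wrong emotion labels.
    """
    correctness = correctness or dict(DEFAULT_CORRECTNESS)
    confusion = {}
    intended_labels = ("neutral", "surprised", "angry")
    for stype, p in correctness.items():
        err = 1.0 - p
        for intended in intended_labels:
            wrong = [l for l in intended_labels if l != intended]
            dist = {intended: p, "other": err * p_other}
            for w in wrong:
                dist[w] = err * (1.0 - p_other) / len(wrong)
            confusion[(intended, stype)] = dist
    return confusion


def generate_ratings(
    confusion: dict | None = None,
    n_videos: int = 81,
    n_raters: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a synthetic rating table from per-stratum confusion distributions.

    Videos cycle through intended emotions and sentence types; each rater
    rates every video, drawing the chosen label independently from the
    stratum's distribution.  Deterministic given the seed.
    """
    confusion = confusion or default_confusion()
    for key, dist in confusion.items():
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"confusion distribution for {key} sums to {total}, not 1")
    rng = np.random.default_rng(seed)
    intended_labels = ("neutral", "surprised", "angry")
    stypes = tuple(sorted({k[1] for k in confusion}))
    rows = []
    for v in range(n_videos):
        intended = intended_labels[v % len(intended_labels)]
        stype = stypes[(v // len(intended_labels)) % len(stypes)]
        dist = confusion[(intended, stype)]
        labels = sorted(dist)
        probs = np.array([dist[l] for l in labels])
        for r in range(n_raters):
            chosen = labels[rng.choice(len(labels), p=probs)]
            rows.append(
                {
                    "video_id": f"v{v:04d}",
                    "intended": intended,
                    "rater_id": f"rater{r + 1}",
                    "chosen": chosen,
                    "sentence_type": stype,
                }
            )
    return pd.DataFrame(rows)
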