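import numpy as np
import pytest

from browkit import features, keypoints_io, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_frame(rng, frame_index=0, n_pose=25):
    """A random but schema-valid frame."""
    def part(n):
        pts = rng.uniform(0, 700, size=(n, 3))
        pts[:, 2] = rng.uniform(0, 1, size=n)
        return np.round(pts, 6)

    return keypoints_io.FrameKeypoints(
        frame_index=frame_index,
        face=part(70),
        left_hand=part(21),
        right_hand=part(21),
        pose=part(n_pose),
    )


def random_series(rng, n_frames=10, video_id="v1"):
    md = keypoints_io.VideoMetadata(
        video_id=video_id, signer_id="D1", group="deaf",
        sentence_id="sent01", emotion="neutral", sentence_type="statement",
    )
    frames = [random_frame(rng, i) for i in range(n_frames)]
    return keypoints_io.KeypointTimeSeries(metadata=md, frames=frames)


@pytest.fixture
def small_config():
    """A small full-pipeline study: 4 signers x 3 sentences x 9 conditions."""
    return synthetic.SyntheticConfig(
        n_signers_deaf=2, n_signers_hearing=2, n_sentences=3,
        frames_per_video=30, n_voided=2, seed=11,
    )


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """The full default synthetic study written to disk, plus its features.

    Generated once per session; used by the end-to-end and acceptance tests.
    """
    out = tmp_path_factory.mktemp("default_study")
    meta, gt = synthetic.generate_study(synthetic.SyntheticConfig(seed=20260922), out)
    return out, meta, gt


@pytest.fixture(scope="session")
def default_study_features(default_study):
    from pathlib import Path

    out, meta, gt = default_study
    summaries = []
    for _, row in meta.iterrows():
        md = synthetic.metadata_from_row(row)
        series = keypoints_io.load_video(Path(out) / md.video_id, md)
        summaries.append(features.extract_features(series))
    return features.summary_table(summaries), gt
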