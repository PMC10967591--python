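import numpy as np
import pytest

from flockmotion import Detection, TrackSet


def build_trackset(rows, fps=18.0, frame_size=(1440, 1080)):
    """TrackSet from (frame, track_id, u, v) tuples; nominal 10x10 boxes."""
    ts = TrackSet(fps=fps, frame_size=frame_size)
    for frame, tid, u, v in rows:
        ts.add(Detection(frame=frame, track_id=tid, centroid=(float(u), float(v)),
                         bbox=(float(u) - 5, float(v) - 5, 10.0, 10.0)))
    return ts


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def make_trackset():
    return build_trackset


def random_homography_matrix(rng, max_tries=100):
    """A well-conditioned random projective matrix, normalized to H[2,2]=1."""
    for _ in range(max_tries):
        h = np.eye(3) + rng.uniform(-0.5, 0.5, (3, 3))
        h[2, :2] = rng.uniform(-0.05, 0.05, 2)
        h[2, 2] = 1.0
        if abs(np.linalg.det(h)) > 0.1:
            return h
    raise RuntimeError("failed to draw an invertible homography")
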