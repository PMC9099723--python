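import numpy as np
import pytest

from wildtrack.io import BoundingBox, Detection, RunConfig


@pytest.fixture
def config():
    return RunConfig(embedding_dim=4, image_width=640, image_height=480)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_detection(frame, left, top, w, h, embedding=None, conf=1.0):
    if embedding is not None:
        embedding = np.asarray(embedding, dtype=float)
        embedding = embedding / np.linalg.norm(embedding)
    return Detection(frame=frame, box=BoundingBox(left, top, w, h), confidence=conf, embedding=embedding)


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)
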