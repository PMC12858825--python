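import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from barcode_screen import VideoTensor


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def static_noise_video(rng):
    """A time-constant video: every frame is the same seeded noise field."""
    frame = rng.uniform(40, 200, (64, 64)).astype(np.float32)
    frames = np.repeat(frame[None], 12, axis=0)
    return VideoTensor(frames=frames, dtype_kind="f32",
                       max_representable=float(frames.max()),
                       source_path="synthetic:static")


def make_uint8_video(rng, T=10, m=64, n=64, lo=30, hi=220):
    frames = rng.integers(lo, hi, (T, m, n)).astype(np.uint8)
    return VideoTensor(frames=frames, dtype_kind="u8", max_representable=255.0,
                       source_path="synthetic:uint8")
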