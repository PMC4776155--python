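import numpy as np
import pytest

from micskit.stack_io import AcquisitionMeta, ImageStack


@pytest.fixture
def simple_meta() -> AcquisitionMeta:
    """Generic metadata for small test stacks (timing loose enough for any shape)."""
    return AcquisitionMeta(pixel_size=0.1, pixel_dwell=1e-6, line_time=1e-3,
                           frame_interval=0.05, beam_waist=0.25, axial_waist=0.75)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_stack(frames: np.ndarray, meta: AcquisitionMeta) -> ImageStack:
    return ImageStack(frames=np.asarray(frames, dtype=np.float64), meta=meta)
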