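import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `naive` importable

from vsdquant.core import AcquisitionSpec
from vsdquant import synth


@pytest.fixture
def small_spec() -> AcquisitionSpec:
    """A desk-scale acquisition: 12x10 frames, 40-frame trial, stim at 10."""
    return AcquisitionSpec(
        frame_height=12,
        frame_width=10,
        n_frames=40,
        stim_frame=10,
        n_baseline_frames=10,
    )


@pytest.fixture
def small_movie(small_spec):
    return synth.make_baseline_movie(small_spec, baseline_mean=100.0, noise_sd=2.0, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
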