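from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from liverseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 48x48x16 phantom with tumors and distractors."""
    cfg = PhantomConfig(
        shape=(48, 48, 16),
        liver_semiaxes=(16.0, 18.0, 6.0),
        tumor_count_range=(2, 2),
        tumor_radius_range=(2.0, 3.5),
        distractor_count=2,
        rng_seed=7,
    )
    return generate_phantom(cfg)


@pytest.fixture
def label_volume_with_mixed_slices():
    """12-slice label volume with known per-slice class content."""
    from liverseg.volume_io import LabelVolume

    labels = np.zeros((8, 8, 12), dtype=np.int16)
    # slices 0-1: background only
    labels[2:6, 2:6, 2] = 1  # slice 2: background + liver
    for z in (3, 5, 7):  # all three classes
        labels[2:6, 2:6, z] = 1
        labels[3:5, 3:5, z] = 2
    labels[1:7, 1:7, 9] = 1  # slice 9: background + liver
    return LabelVolume(labels=labels), [3, 5, 7]
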