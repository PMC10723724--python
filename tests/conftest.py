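import numpy as np
import pytest

from salseg import (Disk, RoiSpec, SceneSpec, SegmentationParams, render)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return SegmentationParams()


@pytest.fixture
def disk_scene_64():
    """Small clean two-phase disk scene with exact ground truth."""
    spec = SceneSpec(shape=(64, 64), objects=(Disk(32, 32, 18, 0.9),),
                     background=0.1, seed=0)
    img, object_masks, combined = render(spec)
    return img, combined


@pytest.fixture
def disk_roi_64():
    return RoiSpec.circle(32, 32, 8)
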