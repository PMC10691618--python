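import numpy as np
import pytest

from rgscal.geometry import PLATE_LABELS
from rgscal.scene import NoiseModel, TrueTransform


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def zero_noise_map():
    return {lbl: NoiseModel.zero() for lbl in PLATE_LABELS}


@pytest.fixture
def a_true_default():
    return TrueTransform.default()


def random_affine(rng, max_rot_deg=60.0, max_trans=500.0, scale_jitter=0.1):
    """A random well-conditioned affine transform for property tests."""
    from rgscal.scene import TrueTransform as TT

    return TT.from_pose(
        rot_x_deg=rng.uniform(-max_rot_deg, max_rot_deg),
        rot_y_deg=rng.uniform(-max_rot_deg, max_rot_deg),
        rot_z_deg=rng.uniform(-max_rot_deg, max_rot_deg),
        translation_mm=tuple(rng.uniform(-max_trans, max_trans, 3)),
        scale=tuple(1.0 + rng.uniform(-scale_jitter, scale_jitter, 3)),
    ).a_true
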