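import numpy as np
import pytest

from actionrep import DatasetConfig, build_conv1_bank, generate_dataset
from actionrep.stcnn import FixedTemplateModel, sample_templates


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale factorial design shared by the synthetic/decoding tests."""
    return DatasetConfig(
        n_actors=3, n_actions=3, viewpoints=(0.0, 90.0),
        clips_per_condition=2, clip_len=10, frame_size=(32, 24),
        fps=5.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_index(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_base_model():
    """Conv1/Pool1 stack with a reduced Gabor bank (8 orientations, 1 speed,
    1 size class) and a two-scale pyramid pooled to one scale channel."""
    bank = build_conv1_bank(speeds=(2.0,), size_classes=((7, 3),))
    return FixedTemplateModel(
        conv1_bank=bank, conv2_bank=bank, pool_groups=None,
        pyramid_factors=(1.0, 0.5), scale_pairs=((0, 1),),
        pool1_region=(2, 2, 1), pool1_stride=(2, 2, 1),
    )


@pytest.fixture(scope="session")
def small_pool1(small_index, small_base_model):
    return [
        (r.key, small_base_model.pool1_responses(small_index.get_clip(r).pixels))
        for r in small_index
    ]


@pytest.fixture(scope="session")
def small_conv2_bank(small_pool1):
    return sample_templates(small_pool1, [(3, 3, 3)], 24, seed=11)
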