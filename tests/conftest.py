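import numpy as np
import pytest

from dynfuse.config import FusionConfig, SynthConfig, TrainSpec
from dynfuse.synth import generate_target_dataset

TINY_DIMS = {"visual_semantic": 12, "pose": 3, "audio": 6, "text": 8}


def tiny_synth(**overrides) -> SynthConfig:
    """A small, fast world for unit tests (not the desk-scale profile)."""
    base = dict(
        n_subjects=24, n_positive=6, utterances_min=4, utterances_max=7,
        dims=dict(TINY_DIMS),
        effect_size={"visual_semantic": 1.5, "pose": 0.2,
                     "audio": 0.6, "text": 0.6},
        subject_sd=0.4, utterance_sd=0.2, noise_sd=0.5,
        pretrain_shift={"visual_semantic": 0.0, "audio": 2.5, "text": 1.0},
        seed=123,
    )
    base.update(overrides)
    return SynthConfig(**base)


def tiny_fusion(**overrides) -> FusionConfig:
    base = dict(d=8, audio_hidden=6, dropout=0.0)
    base.update(overrides)
    return FusionConfig(**base)


def tiny_train(**overrides) -> TrainSpec:
    base = dict(max_epochs=3, patience=2, batch_size=8, seed=5)
    base.update(overrides)
    return TrainSpec(**base)


@pytest.fixture(scope="session")
def tiny_records():
    return generate_target_dataset(tiny_synth())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
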