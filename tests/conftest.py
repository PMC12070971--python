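import numpy as np
import pytest

from sdd.config import EvalConfig, ModelConfig, RunConfig, TrainConfig
from sdd.synthetic import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def tiny_model_config(**overrides) -> ModelConfig:
    """Width-reduced s-variant used for CPU-scale training tests."""
    base = dict(variant="s", width_mult=0.125, input_size=64,
                head={"middle_channel": 32})
    base.update(overrides)
    return ModelConfig(**base)


def tiny_run_config(seed: int = 1, **train_overrides) -> RunConfig:
    train = dict(batch=8, lr=5e-3, warmup_epochs=0, seed=seed)
    train.update(train_overrides)
    return RunConfig(model=tiny_model_config(), train=TrainConfig(**train),
                     eval=EvalConfig(conf_thr=0.1, nms_iou=0.65))


def overfit_scenes(n: int = 8, size: int = 64, n_objects: int = 8,
                   target_or: float = 0.2, seed0: int = 100):
    """Dense scenes for the end-to-end overfit check: 8 mutually occluding
    objects per image, no edge truncation, mild blur."""
    scenes = [generate_scene(SceneSpec(
        n_objects=n_objects, image_size=size, size_range=(18, 30),
        target_or=target_or, edge_fraction=0.0, blur_sigma=0.4, seed=seed0 + i))
        for i in range(n)]
    return [(s.image, np.array([b.as_array() for b in s.annotations.boxes],
                               dtype=np.float32)) for s in scenes]


@pytest.fixture(scope="session")
def train_pairs_8():
    return overfit_scenes()
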