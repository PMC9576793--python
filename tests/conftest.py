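"""Shared fixtures: a small phantom case and a set of briefly trained
micro models (enough for wiring and contract checks; accuracy-critical
training runs live in the tests that need them)."""

import pytest

from stratseg import (
    Genotype,
    PhantomConfig,
    StructureSpec,
    TrainConfig,
    TrainingSet,
    build_registry,
    generate_phantom,
    measure_extents,
    train_branch,
)


def small_phantom_config(seed: int = 5, shape=(32, 48, 48)) -> PhantomConfig:
    """Desk-scale phantom carrying all 42 registry structures."""
    return PhantomConfig(
        shape=shape,
        anchor=StructureSpec(9, (5.0, 8.0), 300.0),
        mid=StructureSpec(19, (3.0, 4.5), 100.0),
        small_hard=StructureSpec(14, (2.0, 3.0), 30.0),
        seed=seed,
    )


@pytest.fixture(scope="session")
def registry():
    return build_registry()


@pytest.fixture(scope="session")
def small_case():
    config = small_phantom_config()
    vol, ss = generate_phantom(config)
    return config, vol, ss


@pytest.fixture(scope="session")
def small_training(small_case, registry):
    _, vol, ss = small_case
    train_set = TrainingSet([(vol, ss)])
    return train_set, measure_extents(train_set, registry)


@pytest.fixture(scope="session")
def micro_genotype():
    return Genotype.uniform("3D", 3, levels=2, base_channels=8)


@pytest.fixture(scope="session")
def micro_models(small_training, micro_genotype):
    """Four briefly-trained branch models on one small phantom."""
    train_set, registry = small_training
    quick = TrainConfig(iterations=10)
    models = {
        "anchor_seg": train_branch(
            train_set, "anchor_seg", micro_genotype, registry, quick, seed=0
        ),
        "mid_seg": train_branch(
            train_set, "mid_seg", micro_genotype, registry, quick, seed=1
        ),
        "sh_detect": train_branch(
            train_set, "sh_detect", micro_genotype, registry, quick, seed=2
        ),
        "sh_seg": train_branch(
            train_set, "sh_seg", micro_genotype, registry, TrainConfig(iterations=20), seed=3
        ),
    }
    return models
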