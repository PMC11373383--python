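"""Shared fixtures: desk-scale simulated datasets and trained models.

Dataset sizes here are deliberately reduced from the full evaluation
protocol (1700/300/2000 windows, 100 epochs) to desk scale so the whole
suite trains real models end to end; the scientific checks compare
relative behaviour (scenario hardness, fusion ordering, architecture
ranking) that survives the reduction.
"""

import numpy as np
import pytest

from dafnet import models, simulate, training

DESK_SPEC = dict(n_train=400, n_val=100, n_test=200)
DESK_EPOCHS = 20


def desk_dataset(scenario_id: str, seed: int = 1, **overrides) -> simulate.Dataset:
    cfg = simulate.load_scenario(scenario_id)
    spec = simulate.DatasetSpec(seed=seed, **{**DESK_SPEC, **overrides})
    return simulate.make_dataset(cfg, spec)


@pytest.fixture(scope="session")
def d1_dataset() -> simulate.Dataset:
    """Mild-bottleneck dataset at desk scale (400/100/200 windows)."""
    return desk_dataset("D1")


@pytest.fixture(scope="session")
def d2_dataset() -> simulate.Dataset:
    """Severe-bottleneck dataset at desk scale."""
    return desk_dataset("D2")


@pytest.fixture(scope="session")
def d4_dataset() -> simulate.Dataset:
    """Old-migration dataset at desk scale."""
    return desk_dataset("D4")


def train_best_model(dataset: simulate.Dataset, seed: int = 1, epochs: int = DESK_EPOCHS):
    model = models.build_1d_model(
        models.best_1d_spec(input_width=dataset.spec.window_width), seed=seed
    )
    ckpt, report = training.train(
        model,
        training.ArraySet.from_windows(dataset.train),
        training.ArraySet.from_windows(dataset.val),
        training.TrainConfig(epochs=epochs, seed=seed),
    )
    return ckpt, report


@pytest.fixture(scope="session")
def d1_checkpoint(d1_dataset):
    """The discovered 1-D architecture trained on the D1 desk dataset."""
    ckpt, report = train_best_model(d1_dataset)
    return ckpt


@pytest.fixture(scope="session")
def d1_test_accuracy(d1_checkpoint, d1_dataset) -> float:
    acc, _ = training.evaluate(
        d1_checkpoint, training.ArraySet.from_windows(d1_dataset.test)
    )
    return acc


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
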