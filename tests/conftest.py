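"""Shared fixtures: benchmark datasets and trained models.

Training fixtures are session-scoped because a scaled-down run of the full
two-phase algorithm takes tens of seconds; several tests interrogate the
same trained model from different angles.
"""

from dataclasses import dataclass

import numpy as np
import pytest

from collabnet.config import CNConfig
from collabnet.data import LabeledDataset, train_test_split
from collabnet.metrics import BinningScheme
from collabnet.synthetic import gen_gaussian_het, gen_sine_1d, gen_weibull
from collabnet.training import joint_train

# Scaled-down protocol used by the training fixtures: half the full
# iteration budget, the benchmark's standard batch size and architecture.
SCALED = dict(pretrain_iters=10_000, joint_iters=10_000)


@dataclass
class Bench:
    dataset: LabeledDataset
    train: LabeledDataset
    test: LabeledDataset
    scheme: BinningScheme


def make_bench(gen, n: int, seed: int) -> Bench:
    ds = gen(n, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    train, test = train_test_split(ds, rng)
    return Bench(ds, train, test, BinningScheme.from_outcomes(ds.outcomes))


@pytest.fixture(scope="session")
def gauss_bench() -> Bench:
    return make_bench(gen_gaussian_het, n=1000, seed=0)


@pytest.fixture(scope="session")
def weibull_bench() -> Bench:
    return make_bench(gen_weibull, n=1000, seed=0)


@pytest.fixture(scope="session")
def sine_bench() -> Bench:
    return make_bench(gen_sine_1d, n=2000, seed=0)


@pytest.fixture(scope="session")
def gauss_cn(gauss_bench: Bench):
    """CN jointly trained on the heteroskedastic Gaussian benchmark."""
    return joint_train(gauss_bench.train, CNConfig(**SCALED, seed=0))


@pytest.fixture(scope="session")
def weibull_cn(weibull_bench: Bench):
    """CN jointly trained on the Weibull benchmark."""
    return joint_train(weibull_bench.train, CNConfig(**SCALED, seed=0))


@pytest.fixture(scope="session")
def sine_cn(sine_bench: Bench):
    """CN jointly trained on the 1-d sine study (n=2000)."""
    return joint_train(sine_bench.train, CNConfig(**SCALED, seed=0))


@pytest.fixture()
def tiny_config() -> CNConfig:
    """Fast configuration for smoke/contract tests (not for accuracy)."""
    return CNConfig(pretrain_iters=300, joint_iters=300, batch_size=32,
                    grid_size=256, seed=0)


@pytest.fixture()
def tiny_dataset() -> LabeledDataset:
    return gen_gaussian_het(120, seed=3)
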