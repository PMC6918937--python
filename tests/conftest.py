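import numpy as np
import pytest

from fatiguenet import (
    ExperimentDesign,
    FatigueTrajectory,
    MIEstimatorConfig,
    WeightedAdjacency,
)


@pytest.fixture(scope="session")
def small_design() -> ExperimentDesign:
    """Two subjects, two epochs per cell: enough for fast pipeline checks."""
    return ExperimentDesign(n_subjects=2, epochs_per_cell=2)


@pytest.fixture(scope="session")
def default_trajectory() -> FatigueTrajectory:
    return FatigueTrajectory.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_adjacency(rng: np.random.Generator, n: int = 19) -> WeightedAdjacency:
    vals = rng.uniform(0.0, 1.0, size=(n, n))
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 0.0)
    labels = tuple(f"ch{i:02d}" for i in range(n))
    return WeightedAdjacency(values=vals, channels=labels)


@pytest.fixture()
def mi_cfg() -> MIEstimatorConfig:
    return MIEstimatorConfig()
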