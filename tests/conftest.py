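import numpy as np
import pytest
from hypothesis import settings

from speedcat.decoding import Ensemble
from speedcat.task import TaskConfig

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def task() -> TaskConfig:
    return TaskConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_iid_ensemble(means, n_neurons: int | None = None, n_eq: int = 10,
                      seed=0, include_direction: bool = False,
                      config: TaskConfig | None = None) -> Ensemble:
    """Ensemble drawn iid Poisson from a (n_neurons, n_classes) mean
    matrix (a scalar mean broadcasts to n_neurons), bypassing session
    assembly."""
    config = config or TaskConfig()
    classes = config.joint_classes(include_direction)
    means = np.atleast_2d(np.asarray(means, dtype=float))
    if means.shape == (1, 1):
        means = np.full((n_neurons, len(classes)), means[0, 0])
    assert means.shape[1] == len(classes)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(means[:, :, None],
                         size=(means.shape[0], len(classes), n_eq))
    return Ensemble(counts=counts, classes=classes,
                    neuron_ids=[f"n{i:03d}" for i in range(means.shape[0])],
                    epoch="post_saccade", n_eq=n_eq,
                    trial_filter="correct_only",
                    reconstructed=np.zeros_like(counts, dtype=bool))
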