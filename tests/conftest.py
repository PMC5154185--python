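import numpy as np
import pytest

from ramforage.maze import VisitSequence, build_flower_array
from ramforage.synth import ExperimentConfig, generate_experiment, dataset_sequences


@pytest.fixture(scope="session")
def octagon():
    return build_flower_array(8, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_260_927)


def make_seq(choices, duration=None, bee="b1", colony="c1", bout=1, phase="training"):
    return VisitSequence(
        bee_id=bee, colony_id=colony, bout_index=bout, phase=phase,
        choices=list(choices), duration_s=duration,
    )


@pytest.fixture(scope="session")
def default_experiment():
    """One default-design synthetic experiment (61 bees, 11 bouts each)."""
    return generate_experiment(ExperimentConfig(), seed=424242)


@pytest.fixture(scope="session")
def default_sequences(default_experiment):
    return dataset_sequences(default_experiment)
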