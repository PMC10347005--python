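import numpy as np
import pytest

from enose_bench.core import Dataset, SensorLayout, Trial
from enose_bench.synthgen import generate_dataset, scenario_config


@pytest.fixture(scope="session")
def tiny_layout():
    return SensorLayout(("A", "B"), 4)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_layout):
    """16 trials, 2 classes, 8 features, hand-constructible geometry."""
    rng = np.random.default_rng(42)
    trials = []
    for c in (1, 2):
        center = np.full(8, float(c))
        for i in range(8):
            feats = center + rng.normal(0, 0.1, 8)
            trials.append(Trial(feats, c, f"c{c}_t{i}"))
    return Dataset(trials, tiny_layout)


@pytest.fixture(scope="session")
def enose_dataset():
    """Standard-shape synthetic e-nose dataset: 6 classes x 12 trials, 240 features."""
    return generate_dataset(scenario_config("overlapping", seed=11), 12)


@pytest.fixture(scope="session")
def separable_dataset():
    return generate_dataset(scenario_config("separable", seed=11), 12)
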