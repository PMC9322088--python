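import numpy as np
import pandas as pd
import pytest

from lipomir import preprocess, quantify
from lipomir.simulate import SimulationConfig, simulate_dataset


def quantify_study(plate, dilutions, spikes):
    """Run the full quantification chain on simulated plate tables."""
    curves = quantify.fit_standard_curves(dilutions)
    copies = quantify.quantify_plate(plate, curves)
    spike_set = quantify.quantify_spike_ins(spikes, curves)
    return quantify.spike_in_normalize(copies, spike_set), curves


def simulate_expression(config: SimulationConfig):
    """Simulate a study and push it through quantification + preprocessing."""
    plate, dilutions, spikes, labels, truth = simulate_dataset(config)
    normed, _ = quantify_study(plate, dilutions, spikes)
    expr = preprocess.preprocess(normed, labels, min_rate=0.90)
    return expr, labels, truth


@pytest.fixture(scope="session")
def two_class_config():
    return SimulationConfig(
        class_sizes={"A": 30, "B": 30},
        n_assays=60,
        n_planted_markers=6,
        planted_log2fc=2.0,
        biological_sd=1.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def two_class_study(two_class_config):
    return simulate_dataset(two_class_config)


@pytest.fixture(scope="session")
def two_class_expression(two_class_config):
    expr, labels, truth = simulate_expression(two_class_config)
    return expr, labels, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_copy_matrix():
    """5 samples x 4 assays with one partially detected assay."""
    from lipomir.containers import CopyMatrix

    samples = [f"s{i}" for i in range(5)]
    assays = [f"m{i}" for i in range(4)]
    gen = np.random.default_rng(7)
    values = pd.DataFrame(
        np.power(2.0, gen.uniform(5, 12, size=(5, 4))), index=samples, columns=assays
    )
    detected = pd.DataFrame(True, index=samples, columns=assays)
    detected.iloc[0, 3] = False
    values.iloc[0, 3] = np.nan
    return CopyMatrix(values=values, detected=detected)
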