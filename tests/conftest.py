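import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import pulkit as pk
from pulkit import expression as ex

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def minimal_scenario():
    return pk.build_fixture_scenario("minimal", seed=11)


@pytest.fixture(scope="session")
def minimal_experiment(minimal_scenario):
    cm, truth = pk.simulate_count_experiment(minimal_scenario)
    return minimal_scenario, cm, truth


@pytest.fixture()
def random_count_matrix():
    """A generic 20-gene x 6-sample matrix (two substrates, triplicate)."""
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(20)]
    samples = [f"s{j}" for j in range(6)]
    counts = pd.DataFrame(
        rng.negative_binomial(5, 0.01, size=(20, 6)), index=genes, columns=samples
    )
    meta = pd.DataFrame(
        {"substrate": ["glucose"] * 3 + ["starch"] * 3, "replicate": [1, 2, 3] * 2},
        index=pd.Index(samples, name="sample_id"),
    )
    lengths = pd.Series(rng.integers(300, 3000, size=20).astype(float), index=genes)
    return ex.CountMatrix(counts, meta, lengths)
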