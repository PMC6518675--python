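import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import lncflux as lx

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_config():
    return lx.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def annotation_truth(sim_config):
    return lx.generate_annotation(sim_config)


@pytest.fixture(scope="session")
def expression(sim_config, annotation_truth):
    annotation, truth = annotation_truth
    return lx.generate_expression(sim_config, annotation, truth)


@pytest.fixture(scope="session")
def design_meta():
    """Balanced 3-tissue x 2-treatment x 3-replicate sample sheet."""
    samples = [f"s{i}" for i in range(18)]
    return pd.DataFrame(
        {
            "tissue": np.repeat(["liver", "aa", "sa"], 6),
            "treatment": (["control"] * 3 + ["high_intake"] * 3) * 3,
            "replicate": [1, 2, 3] * 6,
        },
        index=pd.Index(samples, name="sample_id"),
    )


def make_matrix(log2_values, meta, prefix="f"):
    values = pd.DataFrame(
        np.power(2.0, np.asarray(log2_values, dtype=float)),
        index=[f"{prefix}{i}" for i in range(len(log2_values))],
        columns=meta.index,
    )
    return lx.ExpressionMatrix(values, meta)


@pytest.fixture(scope="session")
def matrix_factory():
    return make_matrix
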