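import numpy as np
import pytest
from hypothesis import settings

from lexasd import synth
from lexasd.schema import default_schema

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def tiny_tagged_dataset(schema):
    """8 labelled, manually tagged documents (strong contrast, short texts)."""
    cfg = synth.benchmark_strong_config(
        schema, n_as=4, n_non_as=4, length_mean=30.0, seed=11
    )
    return synth.generate_corpus(cfg, schema)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
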