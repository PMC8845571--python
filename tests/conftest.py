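import logging

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

logging.getLogger("gradientnet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study: (otu, taxonomy, genes, metadata, truth)."""
    from gradientnet.synthetic import SimulationConfig, assemble_dataset

    return assemble_dataset(SimulationConfig())


@pytest.fixture(scope="session")
def pipeline_result():
    """Full analysis of the default synthetic study, run once per session."""
    import warnings

    from gradientnet.pipeline import run_synthetic_pipeline

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result, truth = run_synthetic_pipeline()
    return result, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
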