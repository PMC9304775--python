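import warnings

import numpy as np
import pytest

import scmntb
from scmntb import pipeline


@pytest.fixture(scope="session")
def default_dataset():
    """Clean 240-cell five-type dataset under the study's default conditions."""
    return scmntb.generate_dataset(scmntb.default_config(seed=11))


@pytest.fixture(scope="session")
def pipeline_report(default_dataset):
    """Full pipeline run on the default dataset, shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.run_pipeline(
            default_dataset.counts, scmntb.PipelineConfig(seed=11)
        )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
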