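import numpy as np
import pytest

from bacplex.pipeline import make_pipeline_dataset, run_pipeline


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study():
    """The full synthetic study: 8 BACs from a 2 Mb genome, scaled 20 kb
    inserts, two mate-pair libraries. Built once per session."""
    return make_pipeline_dataset(seed=7)


@pytest.fixture(scope="session")
def study_result(study):
    """The end-to-end pipeline run over the synthetic study."""
    return run_pipeline(study)
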