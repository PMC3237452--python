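import numpy as np
import pytest

import ischemix as ix


@pytest.fixture(scope="session")
def panel():
    return ix.default_panel()


@pytest.fixture(scope="session")
def default_config():
    return ix.GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def fresh10(default_config):
    """Ten fresh training perfusions under default study conditions."""
    return ix.generate_fresh(default_config, n=10)


@pytest.fixture(scope="session")
def mpca_model(fresh10):
    """Normal-operation model fit on the ten fresh batches."""
    return ix.fit_mpca(fresh10, R=3)


@pytest.fixture(scope="session")
def study(default_config):
    """Combined 10 fresh + 6 warm-ischemic study dataset."""
    return ix.generate_study(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
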