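import numpy as np
import pytest

from lungcea import model, synth


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """Synthetic input bundle (curves, tables, parameter fixture, config)."""
    d = tmp_path_factory.mktemp("bundle")
    synth.make_bundle(d, subgroup_hrs=synth.DEFAULT_SUBGROUP_HRS)
    return d


@pytest.fixture(scope="session")
def inputs(bundle_dir):
    return model.load_inputs(bundle_dir / "config.yaml")


@pytest.fixture(scope="session")
def params(inputs):
    return inputs.params


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
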