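import pytest

import isoanchor as ia


@pytest.fixture(scope="session")
def default_config():
    return ia.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def default_bundle(default_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    ia.simulate_bundle(default_config, out)
    return out


@pytest.fixture(scope="session")
def default_run(default_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    return ia.run_pipeline(ia.RunConfig.from_bundle(default_bundle, out))
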