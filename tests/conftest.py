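import warnings

import pytest

from quotawatch.synth import ScenarioConfig, generate_scenario
from quotawatch.vocab import default_vocabulary

warnings.filterwarnings("ignore", message="ArviZ is undergoing")


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def small_scenario():
    cfg = ScenarioConfig(seed=42, n_species=40, n_parties=10)
    cfg.prepost.n_series = 8
    cfg.updates.n_series = 80
    return cfg


@pytest.fixture(scope="session")
def scenario_dir(small_scenario, tmp_path_factory):
    """A generated synthetic scenario on disk, shared across tests."""
    outdir = tmp_path_factory.mktemp("scenario")
    truth = generate_scenario(small_scenario, outdir)
    return outdir, truth
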