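import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dietfootprint import SyntheticConfig, table2_fixture, write_bundle

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fruit_fixture():
    """Published US fruit worked example (2 cups/d over ten commodities)."""
    return table2_fixture()


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """A small synthetic study bundle shared across pipeline tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = SyntheticConfig(n_countries=3, commodities_per_group=5, seed=11)
    write_bundle(cfg, outdir, withhold=("fruit_c03",))
    return outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
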