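import pytest

from inlandcarbon.pipeline import RunConfig, run_pipeline
from inlandcarbon.synthetic import default_config, generate_inventory


@pytest.fixture(scope="session")
def default_cfg():
    return default_config()


@pytest.fixture(scope="session")
def small_cfg(default_cfg):
    """Down-scaled landscape (2% of body counts) for structural tests."""
    return default_cfg.replace(scale=0.02, seed=7)


@pytest.fixture(scope="session")
def full_inventory(default_cfg):
    """The full calibrated inventory (~4.2M bodies); shared across tests."""
    return generate_inventory(default_cfg)


@pytest.fixture(scope="session")
def full_report(default_cfg):
    """One full-size pipeline run on the calibrated default configuration."""
    return run_pipeline(RunConfig(landscape=default_cfg))
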