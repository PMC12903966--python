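import pytest

from stoichlim import GeneratorConfig, RunConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def cohort18(default_config):
    """The default study design: 3 treatments x 2 depths x 3 replicates."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig()
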