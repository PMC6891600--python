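import pandas as pd
import pytest

from reduvenom.datasets import load_reference_peptides
from reduvenom.synthdata import GeneratorConfig, generate_expression


@pytest.fixture(scope="session")
def reference_peptides() -> pd.DataFrame:
    return load_reference_peptides()


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=20191118)


@pytest.fixture(scope="session")
def expression_fixture(default_config):
    """Default synthetic expression dataset (counts, truth), generated once."""
    return generate_expression(default_config)
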