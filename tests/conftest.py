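import pytest

from vusworm import default_panel
from vusworm.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def seeded_reports():
    """Full pipeline runs over 20 seeds at protocol-scale sample sizes."""
    return [run_pipeline(RunConfig(seed=seed)) for seed in range(20)]
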