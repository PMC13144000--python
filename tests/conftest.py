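import pytest

from sungame import EconomicInputs, bundled_scenario_path, load_scenario


@pytest.fixture(scope="session")
def australia_inputs() -> EconomicInputs:
    """The reference Australian calibration parameters."""
    return load_scenario(bundled_scenario_path()).economic


@pytest.fixture(scope="session")
def australia_config():
    return load_scenario(bundled_scenario_path())
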