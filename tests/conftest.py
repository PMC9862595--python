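import pytest

import bioref as br


@pytest.fixture(scope="session")
def builtins():
    """The four packaged scenarios keyed by name."""
    return {cfg.name: cfg for cfg in br.builtin_scenarios()}


@pytest.fixture(scope="session")
def evaluated(builtins):
    """(ScenarioResult, EconomicResult) per packaged scenario, computed once."""
    return {name: br.evaluate(cfg) for name, cfg in builtins.items()}


@pytest.fixture()
def euc_woa(builtins):
    return builtins["euc_without_acetate"]
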