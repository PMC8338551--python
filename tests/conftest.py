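import pytest

from mobcea import base_case_fixture, evaluate_config


@pytest.fixture(scope="session")
def base_config():
    return base_case_fixture()


@pytest.fixture(scope="session")
def base_result(base_config):
    result, breakdowns = evaluate_config(base_config)
    return result


@pytest.fixture(scope="session")
def base_breakdowns(base_config):
    _, breakdowns = evaluate_config(base_config)
    return breakdowns
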