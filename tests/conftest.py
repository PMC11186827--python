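import pytest

from hazprio import ClassificationRuleSet, fixtures


@pytest.fixture(scope="session")
def rules() -> ClassificationRuleSet:
    return ClassificationRuleSet()


@pytest.fixture(scope="session")
def case1_profiles():
    return fixtures.case1_profiles()


@pytest.fixture(scope="session")
def case3_profiles():
    return fixtures.case3_profiles()
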