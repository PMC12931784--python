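import pytest

from zefmea import importance_scale, load_case_study, rating_scale, reliability_scale


@pytest.fixture(scope="session")
def case():
    return load_case_study()


@pytest.fixture(scope="session")
def scales():
    return {
        "importance": importance_scale(),
        "reliability": reliability_scale(),
        "rating": rating_scale(),
    }
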