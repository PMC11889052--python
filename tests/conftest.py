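import pytest

from ltra import InflationModel, generate_profile, load_fixture


@pytest.fixture
def flat_profile():
    """Flat 100 EUR/year profile over ages 0-100."""
    return generate_profile("log_linear", {"c0": 100.0, "a0": 40, "beta": 0.0})


@pytest.fixture
def no_inflation():
    return InflationModel(0.0)


@pytest.fixture(scope="session")
def paper():
    """The worked-example scenario (40-year-old, 1,720 EUR, 3% inflation)."""
    return load_fixture("paper_example")
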