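import pytest

from themesat import davinci_fixture, resolve_dates


@pytest.fixture(scope="session")
def davinci():
    """Embedded 19-article x 16-theme corpus with mid-month dates resolved."""
    matrix, window = davinci_fixture()
    return resolve_dates(matrix, "mid", window=window), window


@pytest.fixture(scope="session")
def davinci_raw():
    """Fixture before date resolution."""
    return davinci_fixture()
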