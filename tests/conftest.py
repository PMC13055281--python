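import pytest
from hypothesis import HealthCheck, settings

from magprofile import table2_fixture

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_mags():
    mags, _ = table2_fixture()
    return mags


@pytest.fixture(scope="session")
def fixture_percentages():
    _, printed = table2_fixture()
    return printed


@pytest.fixture
def write_tsv(tmp_path):
    """Write a small TSV file and return its path."""

    def _write(name: str, text: str):
        path = tmp_path / name
        path.write_text(text, encoding="utf-8")
        return path

    return _write
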