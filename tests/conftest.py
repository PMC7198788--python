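import pytest

from maglink.synthetic_fixtures import generate_fixture


@pytest.fixture(scope="session")
def fx():
    """The default seeded fixture, shared across the suite (read-only)."""
    return generate_fixture(7)


@pytest.fixture(scope="session")
def fx_dir(fx, tmp_path_factory):
    """The same fixture serialised to disk."""
    d = tmp_path_factory.mktemp("fixture")
    fx.write(d)
    return d
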