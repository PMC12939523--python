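import pytest

from phycolca import synthetic
from phycolca.config import load_config


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Shipped reference fixtures written to a session temp directory."""
    out = tmp_path_factory.mktemp("fixtures")
    synthetic.make_fixtures(out)
    return out


@pytest.fixture(scope="session")
def default_config():
    return load_config(None)
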