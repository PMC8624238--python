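import pytest

from fhdx.config import default_config
from fhdx.synth import build_paper_fixture


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic reference cohort (subjects, pedigrees, annotations)."""
    return build_paper_fixture()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    build_paper_fixture(out)
    return out
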