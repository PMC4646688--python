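import pytest

from gasp.numbering import AlignmentParams, default_scaffold
from gasp.simulate import make_fixture_suite

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def scaffold():
    return default_scaffold()


@pytest.fixture(scope="session")
def params():
    return AlignmentParams()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The deterministic synthetic fixture suite, generated once."""
    outdir = tmp_path_factory.mktemp("fixtures")
    make_fixture_suite(FIXTURE_SEED, outdir)
    return outdir
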