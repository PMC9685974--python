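import pytest

from rvenrich import reanalyze_study_fixture
from rvenrich.cohorts_io import load_study_fixture


@pytest.fixture(scope="session")
def study_fixture():
    return load_study_fixture()


@pytest.fixture(scope="session")
def study_reanalysis():
    """Full exact-test + FDR + concordance reanalysis of the packaged fixture."""
    return reanalyze_study_fixture()
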