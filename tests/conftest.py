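import pytest

from fragpick import molbuilder as mb


@pytest.fixture(scope="session")
def study_set():
    """Source molecules, user fragment layout and the three test peptides."""
    return mb.build_study_set()


@pytest.fixture(scope="session")
def user_ath(study_set):
    sources, user_spec, _targets = study_set
    return mb.build_user_athenaeum(sources, user_spec)


@pytest.fixture(scope="session")
def auto_ath(study_set):
    sources, _user_spec, _targets = study_set
    return mb.build_auto_athenaeum(sources)
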