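import pytest

from atomsmiles import FIXTURE_SETS, load_fixture_set


@pytest.fixture(scope="session", params=sorted(FIXTURE_SETS))
def fixture_set(request):
    """Each bundled molecule set in turn."""
    return load_fixture_set(request.param)


@pytest.fixture(scope="session")
def druglike():
    return load_fixture_set("druglike_small")


@pytest.fixture(scope="session")
def all_fixture_smiles():
    return [s for name in sorted(FIXTURE_SETS)
            for s in load_fixture_set(name)]
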