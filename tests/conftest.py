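import pytest
from hypothesis import settings

from retroprompt.benchmark import default_template_library, generate_fixture
from retroprompt.chem import parse_target
from retroprompt.expand import Stock

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return default_template_library()


@pytest.fixture(scope="session")
def amide_target():
    """N-methyl acetamide with the amide C-N bond prompted to break."""
    return parse_target("[CH3:10][C:1](=[O:2])[NH:3][CH3:11]", break_pairs=[(1, 3)])


@pytest.fixture(scope="session")
def amide_stock():
    return Stock(["CC(=O)O", "CN"])


@pytest.fixture(scope="session")
def small_fixture():
    """A deterministic 10-target synthetic benchmark bundle."""
    return generate_fixture(10, (1, 3), seed=11)
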