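import pytest

from cortevo.datasets_io import load_table1_fixture, packaged_tree_path
from cortevo.orf_evolution import SpeciesTree


@pytest.fixture(scope="session")
def fixture_records():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def primate_tree():
    return SpeciesTree.from_newick(packaged_tree_path())
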