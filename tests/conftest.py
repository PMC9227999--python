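import pytest

from oxvar.ancestral_inference import Phylogeny, infer_panel_ancestral
from oxvar.datasets import SPECIES_TREE_NEWICK, reference_panel


@pytest.fixture(scope="session")
def species_tree() -> Phylogeny:
    return Phylogeny.from_newick_string(SPECIES_TREE_NEWICK)


@pytest.fixture(scope="session")
def ref_panel():
    return reference_panel()


@pytest.fixture(scope="session")
def ref_ancestral(species_tree, ref_panel):
    return infer_panel_ancestral(species_tree, ref_panel)
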