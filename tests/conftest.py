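import numpy as np
import pytest

from discordia.simcoal import SpeciesTreeModel
from discordia.studies import random_additive_tree  # noqa: F401  (fixture helper)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def quartet_model():
    """Asymmetric 4-taxon species tree whose only discordance-relevant
    branch is the (A,B) stem of length 1 (the deeper internal branch is
    effectively infinite)."""
    return SpeciesTreeModel.from_newick("(((A:1,B:1):1.0,C:2.0):8,D:10.0);")


@pytest.fixture
def trio_model():
    """(((P1,P2),P3),O) model used for D-statistic simulations."""
    return SpeciesTreeModel.from_newick("(((P1:1.0,P2:1.0):0.5,P3:1.5):2.0,O:3.5);")


@pytest.fixture
def dfoil_model():
    """Symmetric five-taxon model (((P1,P2),(P3,P4)),O) with the (P1,P2)
    ancestor younger than the (P3,P4) ancestor."""
    return SpeciesTreeModel.from_newick(
        "(((P1:0.5,P2:0.5):1.0,(P3:1.0,P4:1.0):0.5):1.5,O:3.0);"
    )


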