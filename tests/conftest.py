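import numpy as np
import pytest

from pbstyper.models import SubstitutionModel
from pbstyper.synthetic import (GeneCatalog, default_templates,
                                gradient_community,
                                simulate_protein_alignment)
from pbstyper.tree import ReferenceTree

SIX_TAXON_NEWICK = ("((A:0.12,B:0.08):0.06,(C:0.15,D:0.05):0.09,"
                    "(E:0.2,F:0.1):0.04);")


@pytest.fixture(scope="session")
def wag_gamma():
    return SubstitutionModel("WAG", alpha=0.5)


@pytest.fixture(scope="session")
def six_taxon_tree():
    return ReferenceTree.from_newick(SIX_TAXON_NEWICK)


@pytest.fixture(scope="session")
def catalog():
    return GeneCatalog(seed=123)


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def community():
    return gradient_community(rng_seed=2)


@pytest.fixture(scope="session")
def small_alignment(six_taxon_tree, wag_gamma):
    return simulate_protein_alignment(six_taxon_tree, wag_gamma, 300,
                                      rng_seed=17)


def random_binary_tree(taxa, rng, min_len=0.05, max_len=0.25):
    """Random topology with every branch drawn in [min_len, max_len]."""
    nodes = list(taxa)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        l1, l2 = rng.uniform(min_len, max_len, 2)
        nodes.append(f"({a}:{l1:.5f},{b}:{l2:.5f})")
    return ReferenceTree.from_newick(nodes[0] + ";")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20090713)
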