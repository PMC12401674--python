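import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # test helpers

from wquartet import GeneTreeCollection, TaxonIndex, parse_newick


@pytest.fixture
def abcd_index():
    return TaxonIndex(["A", "B", "C", "D"])


@pytest.fixture
def abcd_collection(abcd_index):
    """Three 4-taxon single-tree genes: AB|CD, AB|CD, AC|BD."""
    trees = ["((A,B),(C,D));", "((A,B),(C,D));", "((A,C),(B,D));"]
    genes = [[(parse_newick(t, abcd_index), 1.0)] for t in trees]
    return GeneTreeCollection(abcd_index, genes, "single")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
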