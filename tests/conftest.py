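import dendropy
import pytest
from hypothesis import settings

# derandomized so the suite is reproducible run-to-run
settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def tree_from_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return tree


@pytest.fixture
def cherry():
    """Two-tip tree: A and B split at the root, depth 1."""
    return tree_from_newick("(A:1,B:1):0;")


@pytest.fixture
def three_tip():
    """Ultrametric ((A,B),C): A-B share half their history."""
    return tree_from_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def star3():
    """Star polytomy of three tips."""
    return tree_from_newick("(A:1,B:1,C:1):0;")
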