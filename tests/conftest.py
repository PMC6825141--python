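import pytest

from tautx import read_tree
from tautx.synthetic_data import (ExpressionSimSpec, fixture_tree,
                                  simulate_expression)


@pytest.fixture(scope="session")
def three_taxon_tree():
    return read_tree("((A#1:0.1,B:0.2):0.05,C:0.3);")


@pytest.fixture(scope="session")
def nine_taxon_tree():
    return fixture_tree()


@pytest.fixture(scope="session")
def expression_sim():
    """1,000-gene default simulation (dropout 0), seed 42."""
    return simulate_expression(ExpressionSimSpec(rng_seed=42))
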