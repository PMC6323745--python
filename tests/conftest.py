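import numpy as np
import pytest

from grnkit import (
    BinaryNetwork,
    ExpressionMatrix,
    build_precision,
    sample_expression,
    standardize,
)


def chain_network(p: int) -> BinaryNetwork:
    """Markov-chain structure g1 - g2 - ... - gp."""
    return BinaryNetwork(
        frozenset((i, i + 1) for i in range(p - 1)),
        tuple(f"g{i + 1}" for i in range(p)),
    )


def iid_normal(p: int, n: int, seed: int) -> ExpressionMatrix:
    """Standardized expression with no gene-gene dependence."""
    rng = np.random.default_rng(seed)
    x = ExpressionMatrix(
        rng.standard_normal((p, n)),
        [f"g{i + 1}" for i in range(p)],
        [f"s{i + 1}" for i in range(n)],
    )
    return standardize(x)


@pytest.fixture(scope="session")
def chain10():
    """10-gene chain truth with a large noiseless sample (n=2000)."""
    net = chain_network(10)
    ps = build_precision(net, seed=2)
    x = standardize(sample_expression(ps, 2000, 0.0, seed=3))
    return ps, x


@pytest.fixture(scope="session")
def chain5():
    net = chain_network(5)
    ps = build_precision(net, seed=11)
    x = standardize(sample_expression(ps, 1000, 0.0, seed=21))
    return ps, x
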