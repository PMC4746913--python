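import pytest

from netter import (
    CorruptionSpec,
    SyntheticNetworkSpec,
    extract_top_x,
    simulate_prediction,
)


@pytest.fixture(scope="session")
def small_fixture():
    """An 80-gene synthetic network with a corrupted 150-link prediction."""
    net = SyntheticNetworkSpec(n_genes=80, n_regulators=10, modules=8, seed=3)
    corr = CorruptionSpec(seed=4)
    gold, pred = simulate_prediction(net, corr, x=150)
    return gold, pred, extract_top_x(pred, 150)


@pytest.fixture(scope="session")
def midsize_fixture():
    """A 100-gene network with a 200-link prediction (annealer-scale)."""
    net = SyntheticNetworkSpec(n_genes=100, n_regulators=12, modules=10, seed=31)
    corr = CorruptionSpec(seed=32)
    gold, pred = simulate_prediction(net, corr, x=200)
    return gold, pred, extract_top_x(pred, 200)
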