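"""Shared fixtures: small hand-checkable graphs and synthetic connectomes."""

import numpy as np
import pytest

from commutime import ConnectomeSpec, StructuralConnectome, build_operators, generate_connectome


def connectome_from_weights(weights, lengths=None, hemisphere=None):
    """Build a labelled connectome from a plain weight matrix."""
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    if hemisphere is None:
        hemisphere = ["left"] * (n - n // 2) + ["right"] * (n // 2)
    labels = [f"r{i}" for i in range(n)]
    return StructuralConnectome(
        region_labels=labels,
        hemisphere=list(hemisphere),
        weights=weights,
        lengths=None if lengths is None else np.asarray(lengths, dtype=float),
    )


@pytest.fixture
def two_node():
    """Single edge of weight 5: every walk is one forced step."""
    w = [[0.0, 5.0], [5.0, 0.0]]
    return connectome_from_weights(w, lengths=w)


@pytest.fixture
def path3():
    """Path graph 1-2-3 with unit weights and unit lengths."""
    w = [[0, 1, 0], [1, 0, 1], [0, 1, 0]]
    return connectome_from_weights(w, lengths=w)


@pytest.fixture
def triangle():
    """Complete graph K3 with unit weights."""
    w = [[0, 1, 1], [1, 0, 1], [1, 1, 0]]
    return connectome_from_weights(w, lengths=w)


@pytest.fixture
def star4():
    """Star with center node 0 and three leaves, unit weights."""
    w = np.zeros((4, 4))
    w[0, 1:] = 1.0
    w[1:, 0] = 1.0
    return connectome_from_weights(w, lengths=w)


@pytest.fixture
def small_connectome():
    """20-region synthetic connectome, fixed seed."""
    return generate_connectome(ConnectomeSpec(n_regions=20, seed=11))


@pytest.fixture
def small_ops(small_connectome):
    return build_operators(small_connectome)


def random_connected_connectome(rng, n=None):
    """A random connected weighted graph for property tests."""
    from commutime.core import graph_components

    n = n or rng.integers(4, 31)
    while True:
        w = np.zeros((n, n))
        iu, ju = np.triu_indices(n, k=1)
        present = rng.random(iu.size) < 0.3
        vals = np.where(present, rng.integers(1, 50, iu.size).astype(float), 0.0)
        w[iu, ju] = vals
        w += w.T
        if len(graph_components(w)) == 1:
            return connectome_from_weights(w)
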