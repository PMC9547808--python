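import numpy as np
import pytest
from hypothesis import settings

from gppdn import (
    EntityRef,
    EntityType,
    JumpSpec,
    SubNetwork,
    build_gppdn,
)

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


def gene(symbol: str) -> EntityRef:
    return EntityRef.of(EntityType.GENE, symbol)


def disease(name: str) -> EntityRef:
    return EntityRef.of(EntityType.DISEASE, name)


def gene_layer(name: str, *pairs: tuple[str, str]) -> SubNetwork:
    """Unweighted undirected gene-gene layer from symbol pairs."""
    return SubNetwork.from_edges(
        name, [(gene(a), gene(b), 1.0) for a, b in pairs]
    )


@pytest.fixture
def two_node_net():
    """Single layer, two genes, one edge: M = [[0, 1], [1, 0]]."""
    return build_gppdn([gene_layer("pair", ("A", "B"))])


@pytest.fixture
def two_layer_shared_net():
    """Two gene-gene layers sharing genes A and B."""
    l1 = gene_layer("l1", ("A", "B"), ("A", "C"))
    l2 = gene_layer("l2", ("A", "B"), ("B", "D"))
    return build_gppdn([l1, l2])


@pytest.fixture
def star_net():
    """One layer: hub H connected to five leaves (automorphic leaves)."""
    return build_gppdn(
        [gene_layer("star", *((f"LEAF{i}", "HUB") for i in range(5)))]
    )


@pytest.fixture
def cycle_net():
    """One layer: a 6-cycle; reflection through the seed is an automorphism."""
    n = 6
    return build_gppdn(
        [gene_layer("cycle", *((f"N{i}", f"N{(i + 1) % n}") for i in range(n)))]
    )


def zero_jumps(k: int) -> JumpSpec:
    return JumpSpec(np.zeros((k, k)))
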