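"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written from scratch with dense numpy
loops and must stay independent of the code paths it checks
(transition.assemble_transition and the iterative propagation engine).
"""

from __future__ import annotations

import numpy as np

from gppdn import HeterogeneousNetwork, ToyNetworkParams, generate_toy_gppdn


def dense_transition_oracle(
    net: HeterogeneousNetwork, lam: np.ndarray
) -> np.ndarray:
    """One-pass dense construction of the global transition matrix.

    Row k of diagonal block i: (1 - sum_j I_kj lam_ij) * A_i[k] / sum(A_i[k])
    (all-zero if the within-layer row is zero).  Row k of off-diagonal
    block (i, j): lam_ij * B_ij[k] / sum(B_ij[k]) (all-zero if no cross
    link).  Built straight from edge and cross-link lists.
    """
    n = net.n_nodes
    k_layers = net.n_layers
    offsets = net.layer_offsets

    within = []
    for li, layer in enumerate(net.layers):
        a = np.zeros((layer.n_nodes, layer.n_nodes))
        symmetrize = not (layer.directed and net.respect_direction)
        for s, t, w in layer.edges:
            r, c = layer.index_of(s), layer.index_of(t)
            a[r, c] = max(a[r, c], w)
            if symmetrize:
                a[c, r] = max(a[c, r], w)
        within.append(a)

    bipartite = {
        (i, j): np.zeros((net.layers[i].n_nodes, net.layers[j].n_nodes))
        for i in range(k_layers)
        for j in range(k_layers)
        if i != j
    }
    for link in net.cross_links:
        i, j = link.layer_a, link.layer_b
        ki = net.layers[i].index_of(link.entity)
        kj = net.layers[j].index_of(link.entity)
        bipartite[(i, j)][ki, kj] = link.weight
        bipartite[(j, i)][kj, ki] = link.weight

    m = np.zeros((n, n))
    for i in range(k_layers):
        for k in range(net.layers[i].n_nodes):
            row = offsets[i] + k
            stay = 1.0
            for j in range(k_layers):
                if j != i and bipartite[(i, j)][k].sum() > 0:
                    stay -= lam[i, j]
            wrow = within[i][k]
            if wrow.sum() > 0:
                m[row, offsets[i]: offsets[i + 1]] = stay * wrow / wrow.sum()
            for j in range(k_layers):
                if j == i:
                    continue
                brow = bipartite[(i, j)][k]
                if brow.sum() > 0:
                    m[row, offsets[j]: offsets[j + 1]] = (
                        lam[i, j] * brow / brow.sum()
                    )
    return m


def dense_rwr_oracle(m: np.ndarray, s0: np.ndarray, alpha: float) -> np.ndarray:
    """Exact fixed point of S = alpha M^T S + (1 - alpha) S0 by dense solve."""
    n = m.shape[0]
    return np.linalg.solve(np.eye(n) - alpha * m.T, (1 - alpha) * s0)


def random_small_gppdn(rng: np.random.Generator):
    """A random toy network (2-5 layers, well under 200 global nodes) plus
    a random valid jump matrix; for property sweeps."""
    n_layers = int(rng.integers(2, 6))
    params = ToyNetworkParams(
        n_layers=n_layers,
        genes_per_layer=int(rng.integers(8, 20)),
        other_nodes_per_layer=int(rng.integers(3, 8)),
        within_edge_prob=float(rng.uniform(0.05, 0.3)),
        shared_gene_fraction=float(rng.uniform(0.2, 0.8)),
        planted_partner_degree=int(rng.integers(0, n_layers + 1)),
        noise_edges=int(rng.integers(0, 10)),
        rng_seed=int(rng.integers(2**31)),
    )
    net, truth = generate_toy_gppdn(params)
    lam = random_jump_matrix(n_layers, rng)
    return net, truth, lam


def random_jump_matrix(k: int, rng: np.random.Generator) -> np.ndarray:
    """A random (possibly asymmetric) jump matrix with off-diagonal row
    sums below 1 and zero diagonal."""
    lam = np.zeros((k, k))
    for i in range(k):
        mass = rng.uniform(0.0, 0.9)
        weights = rng.random(k - 1)
        shares = mass * weights / weights.sum()
        lam[i, [j for j in range(k) if j != i]] = shares
    return lam
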