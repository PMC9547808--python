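"""Block transition matrix for a multi-layer random walk.

The global transition matrix M of a K-layer network is a K x K grid of
sub-matrices.  Off-diagonal block (i, j) is the row-normalized bipartite
coupling matrix A_NiNj scaled by the jumping probability lambda_ij; a row
of A_NiNj with no nonzero stays all-zero.  Diagonal block i is the
row-normalized within-layer adjacency A_Ni, with each row k scaled by the
stay probability

    1 - sum_j I_kj * lambda_ij,

where the indicator I_kj is 1 iff row k of A_NiNj has at least one
nonzero (i.e. node k can actually jump to layer j).  Rows therefore sum
to exactly 1 for every node with at least one within-layer edge; nodes
with no within-layer edge get an all-zero diagonal row (the zero-row
convention), which makes their global row substochastic but keeps the
restart iteration contractive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import ConfigError
from .net_model import HeterogeneousNetwork

__all__ = [
    "JumpSpec",
    "TransitionMatrix",
    "row_normalize",
    "offdiagonal_block",
    "diagonal_block",
    "assemble_transition",
]


@dataclass
class JumpSpec:
    """K x K matrix of jumping probabilities lambda_ij in [0, 1).

    lambda_ij is the probability that a walker standing on a node of
    layer i that is linked into layer j crosses to layer j in one step.
    The matrix may be asymmetric; its diagonal is zero; every off-
    diagonal row sum is at most 1, so the stay probability is
    nonnegative even when a node can jump to every other layer.
    """

    lam: np.ndarray

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        if self.lam.ndim != 2 or self.lam.shape[0] != self.lam.shape[1]:
            raise ConfigError(f"jump matrix must be square, got {self.lam.shape}")
        if np.any(np.diag(self.lam) != 0):
            raise ConfigError("jump matrix diagonal must be zero")
        if np.any(self.lam < 0) or np.any(self.lam >= 1):
            raise ConfigError("jumping probabilities must lie in [0, 1)")
        if np.any(self.lam.sum(axis=1) > 1 + 1e-12):
            raise ConfigError(
                "off-diagonal jump mass of a layer must not exceed 1 "
                f"(row sums: {self.lam.sum(axis=1)})"
            )

    @property
    def n_layers(self) -> int:
        return self.lam.shape[0]

    @classmethod
    def uniform(cls, coupling: np.ndarray, total_jump_mass: float = 0.5) -> "JumpSpec":
        """Split a total jump mass equally over each layer's coupled partners.

        ``coupling[i, j]`` is truthy iff layers i and j share at least
        one entity; lambda_ij = total_jump_mass / (number of partners of
        layer i), 0 for uncoupled pairs.
        """
        if not 0 <= total_jump_mass < 1:
            raise ConfigError("total jump mass must lie in [0, 1)")
        coupling = np.asarray(coupling, dtype=bool).copy()
        np.fill_diagonal(coupling, False)
        k = coupling.shape[0]
        lam = np.zeros((k, k))
        for i in range(k):
            partners = np.flatnonzero(coupling[i])
            if partners.size:
                lam[i, partners] = total_jump_mass / partners.size
        return cls(lam)

    @classmethod
    def default_for(
        cls, net: HeterogeneousNetwork, total_jump_mass: float = 0.5
    ) -> "JumpSpec":
        """The package default: jump mass split equally among the layers a
        given layer shares at least one entity with."""
        k = net.n_layers
        coupling = np.zeros((k, k), dtype=bool)
        for link in net.cross_links:
            coupling[link.layer_a, link.layer_b] = True
            coupling[link.layer_b, link.layer_a] = True
        return cls.uniform(coupling, total_jump_mass)


@dataclass
class TransitionMatrix:
    """The assembled global matrix M with block provenance.

    M excludes the restart term (it is alpha-independent); every entry
    lies in [0, 1]; rows sum to 1 except for nodes with no within-layer
    edge, whose diagonal-row mass is deliberately dropped.
    """

    M: sp.csr_matrix
    block_layout: dict[tuple[int, int], tuple[slice, slice]]
    row_sums: np.ndarray = field(repr=False)
    alpha_independent: bool = True

    @property
    def n_nodes(self) -> int:
        return self.M.shape[0]

    @property
    def n_blocks(self) -> int:
        return len(self.block_layout)

    def block(self, i: int, j: int) -> sp.csr_matrix:
        rows, cols = self.block_layout[(i, j)]
        return self.M[rows, cols]

    def mass_deficit(self) -> np.ndarray:
        """Per-row probability mass lost to the zero-row convention."""
        return 1.0 - self.row_sums


def row_normalize(a: sp.spmatrix | np.ndarray) -> sp.csr_matrix:
    """Divide each row of a nonnegative matrix by its sum; all-zero rows
    are left all-zero."""
    a = sp.csr_matrix(a, dtype=float)
    if a.nnz and a.data.min() < 0:
        raise ValueError("row_normalize requires a nonnegative matrix")
    sums = np.asarray(a.sum(axis=1)).ravel()
    scale = np.divide(1.0, sums, out=np.zeros_like(sums), where=sums > 0)
    return sp.diags(scale) @ a


def offdiagonal_block(a_ninj: sp.spmatrix, lambda_ij: float) -> sp.csr_matrix:
    """lambda_ij times the row-normalized bipartite coupling matrix."""
    if not 0 <= lambda_ij < 1:
        raise ConfigError(f"jumping probability must lie in [0, 1), got {lambda_ij}")
    block = sp.csr_matrix(lambda_ij * row_normalize(a_ninj))
    block.eliminate_zeros()
    return block


def diagonal_block(
    a_ni: sp.spmatrix, lambdas_i: np.ndarray, indicators: np.ndarray
) -> sp.csr_matrix:
    """Within-layer block: row k of the row-normalized adjacency scaled by
    the stay probability 1 - sum_j indicators[k, j] * lambdas_i[j].

    ``indicators[k, j]`` must be 1 iff node k has at least one cross link
    into layer j.  Nodes with zero within-layer degree keep an all-zero
    row regardless of their cross links.
    """
    lambdas_i = np.asarray(lambdas_i, dtype=float)
    indicators = np.asarray(indicators, dtype=float)
    stay = 1.0 - indicators @ lambdas_i
    if np.any(stay < -1e-12):
        raise ConfigError(
            "negative stay probability: per-layer jump mass exceeds 1 for "
            "some node"
        )
    stay = np.clip(stay, 0.0, None)
    block = sp.csr_matrix(sp.diags(stay) @ row_normalize(a_ni))
    block.eliminate_zeros()
    return block


def assemble_transition(
    net: HeterogeneousNetwork, jumps: JumpSpec
) -> TransitionMatrix:
    """Assemble the global K x K block transition matrix of a network.

    A K-layer network yields K*K blocks (49 for the seven-layer
    configuration).  Row sums are recorded so callers can audit the mass
    deficit introduced by within-layer-isolated nodes.
    """
    k = net.n_layers
    if jumps.n_layers != k:
        raise ConfigError(
            f"jump matrix is {jumps.n_layers}x{jumps.n_layers} but the "
            f"network has {k} layers"
        )
    # indicator columns per layer: I[k, j] = 1 iff row k of A_NiNj is nonzero
    indicator_cols: list[np.ndarray] = []
    for i in range(k):
        cols = np.zeros((net.layers[i].n_nodes, k))
        for j in range(k):
            if j == i:
                continue
            block = net.bipartite_block(i, j)
            cols[:, j] = (np.asarray(block.sum(axis=1)).ravel() > 0).astype(float)
        indicator_cols.append(cols)

    grid: list[list[sp.spmatrix]] = []
    for i in range(k):
        row_blocks: list[sp.spmatrix] = []
        for j in range(k):
            if i == j:
                blk = diagonal_block(
                    net.layer_adjacency(i), jumps.lam[i], indicator_cols[i]
                )
            else:
                blk = offdiagonal_block(net.bipartite_block(i, j), jumps.lam[i, j])
            row_blocks.append(blk)
        grid.append(row_blocks)
    m = sp.bmat(grid, format="csr")

    offsets = net.layer_offsets
    layout = {
        (i, j): (
            slice(int(offsets[i]), int(offsets[i + 1])),
            slice(int(offsets[j]), int(offsets[j + 1])),
        )
        for i in range(k)
        for j in range(k)
    }
    row_sums = np.asarray(m.sum(axis=1)).ravel()
    return TransitionMatrix(M=m, block_layout=layout, row_sums=row_sums)
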