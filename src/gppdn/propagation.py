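"""Random walk with restart over the global transition matrix.

The score recursion is

    S_{k+1} = alpha * M^T S_k + (1 - alpha) * S_0,

where alpha in [0, 1) weights walk continuation and 1 - alpha is the
restart probability: at every step the walker teleports back to the seed
distribution S_0 with probability 1 - alpha.  Because the spectral
radius of alpha * M^T is at most alpha < 1, the recursion is a
contraction with a unique fixed point, reached here by plain iteration;
:func:`closed_form_solution` solves the fixed-point linear system
directly and serves as an independent oracle for tests.

Propagation is fully deterministic — no randomness lives in this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import InputError
from .net_model import EntityRef, HeterogeneousNetwork
from .transition import TransitionMatrix

logger = logging.getLogger(__name__)

_ORACLE_SIZE_GUARD = 5000


@dataclass
class PropagationConfig:
    """Parameters of the restart iteration.

    alpha: walk-continuation weight in [0, 1); restart probability is
        1 - alpha.  Default 0.7, a conventional network-propagation
        choice.
    tolerance: L1 threshold on successive score changes (default 1e-9).
    max_iterations: iteration cap (default 1000).
    seed_entities: the query entities whose initial mass drives the walk.
    """

    seed_entities: list[EntityRef]
    alpha: float = 0.7
    tolerance: float = 1e-9
    max_iterations: int = 1000

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise InputError(f"alpha must lie in [0, 1), got {self.alpha}")
        if self.tolerance <= 0:
            raise InputError("tolerance must be positive")
        if self.max_iterations < 1:
            raise InputError("max_iterations must be >= 1")
        if not self.seed_entities:
            raise InputError("at least one seed entity is required")


@dataclass
class ScoreVector:
    """Nonnegative scores over global (layer, entity) nodes.

    When every transition row sums to 1, total score mass is conserved at
    sum(S_0) = 1 throughout the iteration; isolated nodes leak mass, so
    the total may fall below 1 but never above.
    """

    scores: np.ndarray = field(repr=False)
    iteration: int = 0
    converged: bool = True
    residual: float = 0.0

    @property
    def n_nodes(self) -> int:
        return self.scores.shape[0]

    @property
    def total_mass(self) -> float:
        return float(self.scores.sum())


def init_seed_vector(
    net: HeterogeneousNetwork, seeds: list[EntityRef]
) -> ScoreVector:
    """Build S_0: unit mass split equally over seed entities, and each
    entity's share split equally over its layer replicas."""
    if not seeds:
        raise InputError("at least one seed entity is required")
    s0 = np.zeros(net.n_nodes)
    share = 1.0 / len(seeds)
    for seed in seeds:
        replicas = net.replicas(seed)
        if not replicas:
            raise InputError(f"seed entity {seed} is absent from every layer")
        for _, gid in replicas:
            s0[gid] += share / len(replicas)
    return ScoreVector(scores=s0)


def propagate_step(
    M: TransitionMatrix | sp.spmatrix,
    s_k: np.ndarray,
    s_0: np.ndarray,
    alpha: float,
) -> np.ndarray:
    """One restart-iteration step: alpha * M^T s_k + (1 - alpha) * s_0."""
    m = M.M if isinstance(M, TransitionMatrix) else M
    if m.shape[0] != s_k.shape[0] or s_k.shape != s_0.shape:
        raise ValueError(
            f"dimension mismatch: M is {m.shape}, S_k {s_k.shape}, S_0 {s_0.shape}"
        )
    if not 0 <= alpha < 1:
        raise InputError(f"alpha must lie in [0, 1), got {alpha}")
    return alpha * (m.T @ s_k) + (1 - alpha) * s_0


def propagate_to_convergence(
    M: TransitionMatrix, s_0: ScoreVector, cfg: PropagationConfig
) -> ScoreVector:
    """Iterate the restart recursion until the L1 change falls below the
    tolerance or the iteration cap is hit (logged, never silent)."""
    mt = sp.csr_matrix(M.M.T)
    s0 = s_0.scores
    s = s0.copy()
    residual = np.inf
    for k in range(1, cfg.max_iterations + 1):
        s_next = cfg.alpha * (mt @ s) + (1 - cfg.alpha) * s0
        residual = float(np.abs(s_next - s).sum())
        s = s_next
        logger.debug("iteration %d: L1 residual %.3e", k, residual)
        if residual < cfg.tolerance:
            return ScoreVector(scores=s, iteration=k, converged=True,
                               residual=residual)
    logger.warning(
        "propagation did not converge in %d iterations (residual %.3e, "
        "tolerance %.3e)", cfg.max_iterations, residual, cfg.tolerance,
    )
    return ScoreVector(
        scores=s, iteration=cfg.max_iterations, converged=False, residual=residual
    )


def closed_form_solution(
    M: TransitionMatrix, s_0: ScoreVector, alpha: float
) -> ScoreVector:
    """Solve (I - alpha M^T) S = (1 - alpha) S_0 exactly by a dense solve.

    Test oracle for the iterative engine; refuses networks above
    5000 nodes, where a dense solve is no longer appropriate.
    """
    n = M.n_nodes
    if n > _ORACLE_SIZE_GUARD:
        raise InputError(
            f"closed-form oracle is limited to {_ORACLE_SIZE_GUARD} nodes, "
            f"got {n}"
        )
    if not 0 <= alpha < 1:
        raise InputError(f"alpha must lie in [0, 1), got {alpha}")
    a = np.eye(n) - alpha * M.M.toarray().T
    s = np.linalg.solve(a, (1 - alpha) * s_0.scores)
    return ScoreVector(scores=s, iteration=0, converged=True, residual=0.0)
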