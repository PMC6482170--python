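"""Reference predictors for comparison with the weighted recommender.

Three classical scorers over the same inputs:

* collaborative filtering (CF) — a similarity-weighted neighbourhood vote;
* random walk with restart (RWR) on the protein similarity network;
* unweighted two-round bipartite allocation (the classical ProbS
  projection, i.e. the recommender with unit edge weights and no
  second-order elimination).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .recommender import eliminate_second_order, final_scores, weight_matrix

logger = logging.getLogger("ibnra")

__all__ = ["BaselineConfig", "cf_predict", "rwr_predict", "lpbni_predict"]


@dataclass(frozen=True)
class BaselineConfig:
    """RWR parameters: restart probability, convergence tolerance, cap."""

    restart_prob: float = 0.5
    rwr_tol: float = 1e-8
    rwr_max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_prob <= 1.0:
            raise ValueError("restart_prob must be in (0, 1]")
        if self.rwr_tol <= 0:
            raise ValueError("rwr_tol must be positive")
        if self.rwr_max_iter < 1:
            raise ValueError("rwr_max_iter must be >= 1")


def cf_predict(I: np.ndarray, sim_p: np.ndarray) -> np.ndarray:
    """Memory-based collaborative filtering over protein similarity.

    ``score(i, j) = sum_k sim_p(i, k) I(k, j) / sum_k sim_p(i, k)`` — the
    similarity-weighted fraction of neighbours interacting with the lncRNA,
    over all proteins.  Proteins with zero total similarity score 0.
    """
    I = np.asarray(I, dtype=float)
    sim_p = np.asarray(sim_p, dtype=float)
    if sim_p.shape != (I.shape[0], I.shape[0]):
        raise ValueError("sim_p shape does not match protein count")
    row_sums = sim_p.sum(axis=1)
    inv = np.where(row_sums > 0, 1.0 / np.where(row_sums > 0, row_sums, 1.0), 0.0)
    return (sim_p @ I) * inv[:, None]


def rwr_predict(
    I: np.ndarray,
    sim_p: np.ndarray,
    config: BaselineConfig = BaselineConfig(),
) -> np.ndarray:
    """Random walk with restart on the protein similarity network.

    The transition matrix is the column-normalized similarity with the
    diagonal zeroed (self-loops would dampen propagation).  Each lncRNA's
    restart vector is its normalized interaction profile; the walk iterates
    ``p <- (1-r) M p + r p0`` to its stationary point.  lncRNAs with no
    training edges get a zero score column with a warning.
    """
    I = np.asarray(I, dtype=float)
    sim_p = np.asarray(sim_p, dtype=float)
    if sim_p.shape != (I.shape[0], I.shape[0]):
        raise ValueError("sim_p shape does not match protein count")
    M = sim_p.copy()
    np.fill_diagonal(M, 0.0)
    col = M.sum(axis=0)
    M = M / np.where(col > 0, col, 1.0)[None, :]

    r = config.restart_prob
    edge_counts = I.sum(axis=0)
    cold = edge_counts == 0
    if cold.any():
        logger.warning("RWR: %d lncRNAs have no training edges; zero columns", int(cold.sum()))
    P0 = I / np.where(cold, 1.0, edge_counts)[None, :]
    P = P0.copy()
    for _ in range(config.rwr_max_iter):
        P_next = (1.0 - r) * (M @ P) + r * P0
        if np.abs(P_next - P).sum(axis=0).max() < config.rwr_tol:
            P = P_next
            break
        P = P_next
    P[:, cold] = 0.0
    return P


def lpbni_predict(I: np.ndarray) -> np.ndarray:
    """Unweighted two-round bipartite allocation (classical ProbS).

    Equivalent to running the weighted recommender with identity
    similarity matrices and ``alpha = 0``: the initial scores reduce to the
    binary interaction matrix itself and the projection weight is
    ``W(i, j) = (1/deg p_j) sum_k I(i, k) I(j, k) / deg l_k``.
    """
    I = np.asarray(I, dtype=float)
    W = weight_matrix(I)
    return final_scores(eliminate_second_order(W, 0.0), I)
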