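"""Similarity-weighted two-round resource allocation with second-order
correlation elimination — the recommender proper.

The method scores candidate proteins for each lncRNA by spreading resource
mass over the known-interaction bipartite graph (a ProbS-style two-round
allocation), except that the unit resources of the classical algorithm are
replaced by similarity-derived initial scores:

1. ``SP`` and ``SL`` place a similarity-weighted score on every known edge
   (and only on known edges); ``Sini = gamma*SP + (1-gamma)*SL`` blends the
   protein-side and lncRNA-side views.
2. The two-round allocation — proteins push their score to the lncRNAs they
   interact with, which push it back to proteins — collapses into a single
   protein-protein weight matrix ``W`` applied to ``Sini`` column by column.
   ``W`` is column-stochastic over proteins with positive degree, so each
   column's score mass is conserved.
3. Proteins sharing an lncRNA are also correlated indirectly through
   intermediary proteins; ``W' = W + alpha*W**2`` with ``alpha`` in (-1, 0]
   subtracts that second-order redundancy.  The final scores are
   ``Sfin' = W' @ Sini``, and proteins are recommended to each lncRNA in
   descending score order.

With ``alpha`` negative, entries of ``W'`` (hence of the final scores) can
be negative; ranking uses the raw scores without clipping.  Zero-degree
proteins or lncRNAs — possible when cross-validation masks edges —
contribute and receive nothing by convention; no division by zero occurs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("ibnra")

__all__ = [
    "PredictorConfig",
    "protein_side_scores",
    "lncrna_side_scores",
    "initial_scores",
    "protein_degrees",
    "lncrna_degrees",
    "weight_matrix",
    "two_round_allocation",
    "eliminate_second_order",
    "final_scores",
    "predict",
    "rank_candidates",
]


@dataclass(frozen=True)
class PredictorConfig:
    """Tunable parameters of the recommender.

    gamma : weight of the protein-side score matrix in ``Sini`` (0..1).
    alpha : second-order elimination strength, in (-1, 0]; 0 disables it.
    beta_prime_* : Gaussian-kernel bandwidth adjustments per axis.
    exclude_known : drop known interactions from ranked candidate lists.
    literal_denominator : use the mechanical row-index reading of the
        lncRNA-side normalizer instead of normalizing by total similarity
        to the scored lncRNA (comparison switch; requires np <= nl).
    """

    gamma: float = 0.5
    alpha: float = -0.70
    beta_prime_protein: float = 1.0
    beta_prime_lncrna: float = 1.0
    exclude_known: bool = True
    literal_denominator: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if not -1.0 < self.alpha <= 0.0:
            raise ValueError(f"alpha must be in (-1, 0], got {self.alpha}")
        if self.beta_prime_protein <= 0 or self.beta_prime_lncrna <= 0:
            raise ValueError("kernel bandwidth adjustments must be positive")


def protein_side_scores(I: np.ndarray, sim_p: np.ndarray) -> np.ndarray:
    """Resource scores on known edges from the protein-similarity view.

    ``SP(i, j)`` is the similarity-weighted fraction of proteins (similar
    to ``p_i``) that interact with ``l_j``, placed only where ``I = 1``.
    Entries lie in [0, 1].
    """
    I = np.asarray(I, dtype=float)
    sim_p = np.asarray(sim_p, dtype=float)
    if sim_p.shape != (I.shape[0], I.shape[0]):
        raise ValueError("sim_p shape does not match protein count")
    row_sums = sim_p.sum(axis=1)
    if (row_sums <= 0).any():
        raise ValueError("protein similarity has a non-positive row sum")
    return (sim_p @ I) / row_sums[:, None] * I


def lncrna_side_scores(
    I: np.ndarray, sim_l: np.ndarray, literal_denominator: bool = False
) -> np.ndarray:
    """Resource scores on known edges from the lncRNA-similarity view.

    ``SL(i, j)`` sums the similarity of ``l_j`` to the lncRNAs that ``p_i``
    interacts with, normalized by the total similarity to ``l_j``, placed
    only where ``I = 1``.  A zero normalizer yields 0 with a warning.

    ``literal_denominator`` reproduces a mechanical alternative reading in
    which the normalizer is indexed by the protein's row number instead of
    the scored lncRNA; it exists for comparison only and requires the
    protein count not to exceed the lncRNA count.
    """
    I = np.asarray(I, dtype=float)
    sim_l = np.asarray(sim_l, dtype=float)
    if sim_l.shape != (I.shape[1], I.shape[1]):
        raise ValueError("sim_l shape does not match lncRNA count")
    numer = I @ sim_l  # (np, nl): sum_k I(i,k) * sim_l(k,j)
    col_sums = sim_l.sum(axis=0)
    if literal_denominator:
        n_p, n_l = I.shape
        if n_p > n_l:
            raise ValueError(
                "literal denominator needs at most as many proteins as lncRNAs"
            )
        denom = col_sums[:n_p][:, None]  # indexed by protein row
    else:
        denom = col_sums[None, :]  # indexed by scored lncRNA
    zero = denom == 0
    if zero.any():
        logger.warning("lncRNA-side normalizer zero for %d entries", int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        SL = np.where(zero, 0.0, numer / np.where(zero, 1.0, denom))
    return SL * I


def initial_scores(SP: np.ndarray, SL: np.ndarray, gamma: float = 0.5) -> np.ndarray:
    """Blend the two score matrices: ``Sini = gamma*SP + (1-gamma)*SL``."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    SP = np.asarray(SP, dtype=float)
    SL = np.asarray(SL, dtype=float)
    if SP.shape != SL.shape:
        raise ValueError("SP and SL shapes differ")
    return gamma * SP + (1.0 - gamma) * SL


def protein_degrees(Sini: np.ndarray) -> np.ndarray:
    """Weighted degree of each protein: row sums of ``Sini``."""
    return np.asarray(Sini, dtype=float).sum(axis=1)


def lncrna_degrees(Sini: np.ndarray) -> np.ndarray:
    """Weighted degree of each lncRNA: column sums of ``Sini``."""
    return np.asarray(Sini, dtype=float).sum(axis=0)


def weight_matrix(Sini: np.ndarray) -> np.ndarray:
    """Protein-protein weight matrix of the two-round allocation.

    ``W(i, j) = (1/d(p_j)) * sum_k Sini(i, k) * Sini(j, k) / d(l_k)``.
    Terms with ``d(l_k) = 0`` contribute nothing; columns for proteins with
    ``d(p_j) = 0`` are all zero.  Over proteins with positive degree each
    column sums to 1.
    """
    Sini = np.asarray(Sini, dtype=float)
    if (Sini < 0).any():
        raise ValueError("Sini must be non-negative")
    d_l = lncrna_degrees(Sini)
    d_p = protein_degrees(Sini)
    inv_dl = np.where(d_l > 0, 1.0 / np.where(d_l > 0, d_l, 1.0), 0.0)
    W = (Sini * inv_dl[None, :]) @ Sini.T
    inv_dp = np.where(d_p > 0, 1.0 / np.where(d_p > 0, d_p, 1.0), 0.0)
    return W * inv_dp[None, :]


def two_round_allocation(Sini: np.ndarray, k: int) -> np.ndarray:
    """Explicit two-round allocation for one lncRNA column.

    Follows the per-run iterative definition literally: proteins start with
    ``s0(p_i) = Sini(i, k)``, push scores to lncRNAs in proportion to their
    edge weights over protein degree, and receive them back over lncRNA
    degree.  Returns the per-protein score vector ``s2``.

    This loop form exists as a readable cross-check of the production
    matrix path (``weight_matrix(Sini) @ Sini``), to which it is equal.
    """
    Sini = np.asarray(Sini, dtype=float)
    n_p, n_l = Sini.shape
    if not 0 <= k < n_l:
        raise IndexError(f"lncRNA index {k} out of range")
    d_p = protein_degrees(Sini)
    d_l = lncrna_degrees(Sini)
    s0 = Sini[:, k].copy()

    # round 1: each lncRNA collects from the proteins on its edges
    s1 = np.zeros(n_l)
    for m in range(n_l):
        for j in range(n_p):
            if d_p[j] > 0:
                s1[m] += Sini[j, m] * s0[j] / d_p[j]

    # round 2: each protein collects back from the lncRNAs on its edges
    s2 = np.zeros(n_p)
    for i in range(n_p):
        for m in range(n_l):
            if d_l[m] > 0:
                s2[i] += Sini[i, m] * s1[m] / d_l[m]
    return s2


def eliminate_second_order(W: np.ndarray, alpha: float) -> np.ndarray:
    """Subtract second-order correlations: ``W' = W + alpha * W @ W``.

    ``alpha`` must lie in (-1, 0]; at 0 the weight matrix is unchanged.
    Column sums over positive-degree proteins become ``1 + alpha``.
    """
    if not -1.0 < alpha <= 0.0:
        raise ValueError(f"alpha must be in (-1, 0], got {alpha}")
    W = np.asarray(W, dtype=float)
    return W + alpha * (W @ W)


def final_scores(W_prime: np.ndarray, Sini: np.ndarray) -> np.ndarray:
    """Final score matrix ``Sfin' = W' @ Sini``."""
    W_prime = np.asarray(W_prime, dtype=float)
    Sini = np.asarray(Sini, dtype=float)
    if W_prime.shape[1] != Sini.shape[0]:
        raise ValueError(
            f"shape mismatch: W' {W_prime.shape} @ Sini {Sini.shape}"
        )
    return W_prime @ Sini


def predict(
    I: np.ndarray,
    sim_p: np.ndarray,
    sim_l: np.ndarray,
    config: PredictorConfig = PredictorConfig(),
) -> np.ndarray:
    """Full scoring pipeline from interactions and similarities.

    Returns the final score matrix (proteins x lncRNAs); higher means a
    more strongly recommended interaction.
    """
    SP = protein_side_scores(I, sim_p)
    SL = lncrna_side_scores(I, sim_l, config.literal_denominator)
    Sini = initial_scores(SP, SL, config.gamma)
    W = weight_matrix(Sini)
    W_prime = eliminate_second_order(W, config.alpha)
    return final_scores(W_prime, Sini)


def rank_candidates(
    scores: np.ndarray,
    k: int,
    protein_ids: list[str],
    I: np.ndarray | None = None,
    exclude_known: bool = True,
) -> list[tuple[str, float]]:
    """Ranked (protein_id, score) list for lncRNA column ``k``.

    Descending score; ties broken by protein id (stable, lexicographic).
    With ``exclude_known`` proteins already interacting with the lncRNA
    (per ``I``) are omitted.
    """
    scores = np.asarray(scores, dtype=float)
    if not 0 <= k < scores.shape[1]:
        raise IndexError(f"lncRNA index {k} out of range")
    candidates = range(scores.shape[0])
    if exclude_known:
        if I is None:
            raise ValueError("exclude_known requires the interaction matrix")
        candidates = [i for i in candidates if I[i, k] == 0]
    order = sorted(candidates, key=lambda i: (-scores[i, k], protein_ids[i]))
    return [(protein_ids[i], float(scores[i, k])) for i in order]
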