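"""Protein and lncRNA similarity matrices.

Two sources per axis, integrated entrywise:

* proteins — degree-normalized PPI scores (``AP'``) combined with a
  Gaussian interaction-profile kernel over the rows of ``I`` (``KP``);
* lncRNAs — absolute Pearson correlation of tissue expression profiles
  (``AL``) combined with the same kernel over the columns of ``I`` (``KL``).

The Gaussian interaction-profile kernel is
``K(i, j) = exp(-beta * ||X_i - X_j||^2)`` with bandwidth
``beta = beta' / mean_i ||X_i||^2``, so the scale adapts to the density of
the interaction matrix; ``beta' = 1`` is the conventional default.

During cross-validation the kernels must be rebuilt from the fold's masked
interaction matrix — their profiles are the interactions themselves, so
building them from the full matrix would leak test edges.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "normalize_ppi",
    "gaussian_profile_kernel",
    "expression_similarity",
    "integrate_protein_similarity",
    "integrate_lncrna_similarity",
    "build_similarities",
]

_SYM_TOL = 1e-10


def normalize_ppi(AP: np.ndarray) -> np.ndarray:
    """Degree-normalize a symmetric non-negative PPI score matrix.

    ``AP'(i, j) = AP(i, j) / sqrt(R(i) * R(j))`` with ``R(i)`` the i-th row
    sum.  Proteins with no listed interactions (``R = 0``) get zero rows and
    columns rather than a division by zero.
    """
    AP = np.asarray(AP, dtype=float)
    if AP.ndim != 2 or AP.shape[0] != AP.shape[1]:
        raise ValueError("AP must be square")
    if not np.allclose(AP, AP.T, atol=_SYM_TOL):
        raise ValueError("AP must be symmetric")
    if (AP < 0).any():
        raise ValueError("AP must be non-negative")
    R = AP.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(R > 0, 1.0 / np.sqrt(np.where(R > 0, R, 1.0)), 0.0)
    return AP * np.outer(inv_sqrt, inv_sqrt)


def gaussian_profile_kernel(
    I: np.ndarray, axis: str, beta_prime: float = 1.0
) -> np.ndarray:
    """Gaussian interaction-profile kernel over one axis of ``I``.

    Parameters
    ----------
    I : binary matrix (proteins x lncRNAs)
    axis : {"protein", "lncrna"}
        "protein" uses rows of ``I`` as profiles; "lncrna" uses columns.
    beta_prime : float
        Bandwidth adjustment; the effective bandwidth is
        ``beta_prime / mean squared profile norm``.

    Raises
    ------
    ValueError
        If ``I`` has no interactions (bandwidth undefined) or
        ``beta_prime <= 0``.
    """
    if beta_prime <= 0:
        raise ValueError("beta_prime must be positive")
    I = np.asarray(I, dtype=float)
    if axis == "protein":
        X = I
    elif axis == "lncrna":
        X = I.T
    else:
        raise ValueError(f"axis must be 'protein' or 'lncrna', got {axis!r}")
    mean_sq_norm = (X ** 2).sum(axis=1).mean()
    if mean_sq_norm == 0:
        raise ValueError("bandwidth undefined: interaction matrix is all zero")
    beta = beta_prime / mean_sq_norm
    sq_dists = squareform(pdist(X, metric="sqeuclidean"))
    K = np.exp(-beta * sq_dists)
    np.fill_diagonal(K, 1.0)
    return K


def expression_similarity(E: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation between lncRNA expression profiles.

    Constant profiles (zero standard deviation) have undefined correlation;
    they are assigned similarity 0 to every other lncRNA, with the diagonal
    forced to 1.  The sample-covariance convention is used for the
    intermediates; |r| is the same under either convention.
    """
    E = np.asarray(E, dtype=float)
    if E.ndim != 2 or E.shape[1] < 2:
        raise ValueError("expression matrix needs at least 2 tissue columns")
    sd = E.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        AL = np.abs(np.corrcoef(E))
    AL[degenerate, :] = 0.0
    AL[:, degenerate] = 0.0
    AL = np.nan_to_num(AL, nan=0.0)
    np.fill_diagonal(AL, 1.0)
    return AL


def _check_same_shape(A: np.ndarray, B: np.ndarray) -> None:
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")


def integrate_protein_similarity(AP_norm: np.ndarray, KP: np.ndarray) -> np.ndarray:
    """Combine normalized PPI scores with the kernel similarity.

    Entrywise: the average ``(AP' + KP) / 2`` where a PPI score exists
    (``AP' != 0``), the kernel alone otherwise.  The kernel thus fills in
    for protein pairs with no recorded PPI evidence.
    """
    AP_norm = np.asarray(AP_norm, dtype=float)
    KP = np.asarray(KP, dtype=float)
    _check_same_shape(AP_norm, KP)
    return np.where(AP_norm != 0, (AP_norm + KP) / 2.0, KP)


def integrate_lncrna_similarity(AL: np.ndarray, KL: np.ndarray) -> np.ndarray:
    """Combine expression similarity with the kernel: unconditional average."""
    AL = np.asarray(AL, dtype=float)
    KL = np.asarray(KL, dtype=float)
    _check_same_shape(AL, KL)
    return (AL + KL) / 2.0


def build_similarities(
    I: np.ndarray,
    AP: np.ndarray | None = None,
    E: np.ndarray | None = None,
    beta_prime_protein: float = 1.0,
    beta_prime_lncrna: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Build the integrated (Sim^P, Sim^L) pair from an interaction matrix.

    ``AP`` (PPI scores) and ``E`` (expression profiles) are optional; when
    absent the corresponding axis falls back to the kernel similarity alone
    — for the protein axis that is exactly the ``AP' = 0`` branch, and for
    the lncRNA axis the plain average with ``AL = KL`` degenerates to
    ``KL``.
    """
    KP = gaussian_profile_kernel(I, "protein", beta_prime_protein)
    KL = gaussian_profile_kernel(I, "lncrna", beta_prime_lncrna)
    sim_p = integrate_protein_similarity(normalize_ppi(AP), KP) if AP is not None else KP
    sim_l = integrate_lncrna_similarity(expression_similarity(E), KL) if E is not None else KL
    return sim_p, sim_l
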