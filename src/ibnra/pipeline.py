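"""Fitting and scoring entry points shared by the CLI, the evaluation
harness and the examples.

``fit_recommender`` builds every intermediate of the weighted recommender
from an interaction matrix (plus optional PPI and expression inputs);
``score_matrix`` dispatches any supported method name to a full score
matrix over the same network.
"""

from __future__ import annotations

import numpy as np

from . import similarity
from .baselines import BaselineConfig, cf_predict, lpbni_predict, rwr_predict
from .recommender import (
    PredictorConfig,
    eliminate_second_order,
    final_scores,
    initial_scores,
    lncrna_side_scores,
    protein_side_scores,
    weight_matrix,
)

__all__ = ["METHODS", "fit_recommender", "score_matrix"]

METHODS = ("ibnra", "cf", "rwr", "lpbni")


def fit_recommender(
    I: np.ndarray,
    ppi: np.ndarray | None = None,
    expression_profiles: np.ndarray | None = None,
    config: PredictorConfig = PredictorConfig(),
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Build (Sini, W) from an interaction matrix and auxiliary inputs.

    Also returns the intermediate matrices whose support must match the
    training interactions (used by the evaluation leakage guard).
    """
    sim_p, sim_l = similarity.build_similarities(
        I, ppi, expression_profiles,
        beta_prime_protein=config.beta_prime_protein,
        beta_prime_lncrna=config.beta_prime_lncrna,
    )
    SP = protein_side_scores(I, sim_p)
    SL = lncrna_side_scores(I, sim_l, config.literal_denominator)
    Sini = initial_scores(SP, SL, config.gamma)
    W = weight_matrix(Sini)
    return Sini, W, {"I": np.asarray(I, dtype=float), "SP": SP, "SL": SL, "Sini": Sini}


def score_matrix(
    I: np.ndarray,
    method: str = "ibnra",
    ppi: np.ndarray | None = None,
    expression_profiles: np.ndarray | None = None,
    config: PredictorConfig = PredictorConfig(),
    baseline_config: BaselineConfig = BaselineConfig(),
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Score every (protein, lncRNA) pair with the named method.

    Returns the score matrix and the intermediates whose support is
    restricted to the known interactions.
    """
    if method == "ibnra":
        Sini, W, parts = fit_recommender(I, ppi, expression_profiles, config)
        return final_scores(eliminate_second_order(W, config.alpha), Sini), parts
    if method == "lpbni":
        return lpbni_predict(I), {"I": np.asarray(I, dtype=float)}
    if method in ("cf", "rwr"):
        sim_p, _ = similarity.build_similarities(
            I, ppi, None,
            beta_prime_protein=config.beta_prime_protein,
            beta_prime_lncrna=config.beta_prime_lncrna,
        )
        if method == "cf":
            return cf_predict(I, sim_p), {"I": np.asarray(I, dtype=float)}
        return rwr_predict(I, sim_p, baseline_config), {"I": np.asarray(I, dtype=float)}
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
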