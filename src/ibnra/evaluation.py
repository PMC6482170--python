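"""Cross-validated evaluation of interaction predictors.

Known edges are partitioned into folds (leave-one-out or k-fold).  In each
fold the test edges are zeroed out of the interaction matrix and *every*
model quantity — kernel similarities, initial scores, the weight matrix —
is recomputed from the masked matrix, so no test information leaks into
training.  Test edges are scored as positives; the negative class is every
(protein, lncRNA) pair absent from the full network, restricted to lncRNAs
that have a test edge in the fold.  Pooled scores and labels feed a
rank-based ROC/PR analysis plus thresholded confusion-matrix metrics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

from .baselines import BaselineConfig
from .network import BipartiteNetwork, ExpressionProfileTable
from .pipeline import METHODS, fit_recommender, score_matrix
from .recommender import PredictorConfig, eliminate_second_order, final_scores

logger = logging.getLogger("ibnra")

__all__ = [
    "METHODS",
    "FoldPlan",
    "EvalReport",
    "make_folds",
    "run_cv",
    "alpha_sweep",
    "roc_auc",
    "pr_aupr",
    "binary_metrics",
    "BinaryMetrics",
]

@dataclass(frozen=True)
class FoldPlan:
    """A seeded partition of the known edges into disjoint test folds.

    ``folds`` holds arrays of edge indices into ``edges``, a fixed
    (protein_index, lncrna_index) listing of the known interactions.
    """

    scheme: str
    k: int
    seed: int
    edges: np.ndarray = field(repr=False)  # (n_edges, 2) int array
    folds: list[np.ndarray] = field(repr=False)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def make_folds(
    net: BipartiteNetwork, scheme: str = "loocv", k: int = 10, seed: int = 0
) -> FoldPlan:
    """Shuffle the known edges with ``seed`` and split them into folds.

    ``scheme="loocv"`` puts one edge per fold (``k`` is ignored);
    ``scheme="kfold"`` splits as evenly as possible into ``k`` folds.
    """
    edges = np.argwhere(net.I == 1)  # row-major: deterministic base order
    n = len(edges)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    if scheme == "loocv":
        folds = [np.array([p]) for p in perm]
    elif scheme == "kfold":
        if k < 2:
            raise ValueError("k must be >= 2")
        if k > n:
            raise ValueError(f"k={k} exceeds the number of edges ({n})")
        folds = [f for f in np.array_split(perm, k)]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return FoldPlan(scheme=scheme, k=(1 if scheme == "loocv" else k), seed=seed,
                    edges=edges, folds=folds)


@dataclass
class BinaryMetrics:
    """Confusion-matrix metrics at a single score threshold."""

    pre: float
    sen: float
    acc: float
    f1: float
    mcc: float
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    degenerate: list[str] = field(default_factory=list)


@dataclass
class EvalReport:
    """Pooled cross-validation outcome for one method."""

    method: str
    scheme: str
    scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    auc: float = np.nan
    aupr: float = np.nan
    metrics: BinaryMetrics | None = None
    per_fold_auc: list[float] = field(default_factory=list)
    roc: tuple[np.ndarray, np.ndarray] = field(default=None, repr=False)
    pr: tuple[np.ndarray, np.ndarray] = field(default=None, repr=False)
    max_masked_leak: float = 0.0

    def summary(self) -> dict:
        d = {
            "method": self.method,
            "scheme": self.scheme,
            "n_scored": int(len(self.scores)),
            "n_positive": int(self.labels.sum()),
            "auc": self.auc,
            "aupr": self.aupr,
            "per_fold_auc": self.per_fold_auc,
            "max_masked_leak": self.max_masked_leak,
        }
        if self.metrics is not None:
            d["metrics"] = asdict(self.metrics)
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.summary(), fh, indent=2)
            fh.write("\n")


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def roc_auc(scores, labels) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC curve and its area.

    The area equals the Mann-Whitney pairwise statistic (ties count 1/2).
    Returns ``((fpr, tpr), auc)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    return (fpr, tpr), float(np.trapezoid(tpr, fpr))


def pr_aupr(scores, labels) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Precision-recall curve and its step-wise (non-interpolated) area.

    The area is the average-precision summation
    ``sum_n (R_n - R_{n-1}) P_n``; returns ``((recall, precision), aupr)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.sum(labels) == 0:
        raise ValueError("at least one positive is required")
    precision, recall, _ = precision_recall_curve(labels, scores)
    return (recall, precision), float(average_precision_score(labels, scores))


def binary_metrics(scores, labels, threshold_rule: str = "max_f1") -> BinaryMetrics:
    """Thresholded confusion-matrix metrics.

    ``threshold_rule`` is ``"max_f1"`` (default), ``"youden"`` (maximize
    TPR - FPR), or ``"fixed:<x>"``.  A prediction is positive when
    ``score >= threshold``.  Metrics with a zero denominator are reported
    as 0 and flagged in ``degenerate``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)

    if threshold_rule == "max_f1":
        precision, recall, thresholds = precision_recall_curve(labels, scores)
        with np.errstate(divide="ignore", invalid="ignore"):
            f1 = np.where(precision + recall > 0,
                          2 * precision * recall / (precision + recall), 0.0)
        # last curve point (recall 0) has no threshold
        best = int(np.nanargmax(f1[:-1]))
        threshold = float(thresholds[best])
    elif threshold_rule == "youden":
        fpr, tpr, thresholds = roc_curve(labels, scores)
        best = int(np.argmax(tpr - fpr))
        threshold = float(min(thresholds[best], scores.max()))
    elif threshold_rule.startswith("fixed:"):
        threshold = float(threshold_rule.split(":", 1)[1])
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")

    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))

    degenerate: list[str] = []

    def _ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    pre = _ratio(tp, tp + fp, "pre")
    sen = _ratio(tp, tp + fn, "sen")
    acc = (tp + tn) / (tp + tn + fp + fn)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "f1")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        degenerate.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return BinaryMetrics(pre=pre, sen=sen, acc=acc, f1=f1, mcc=float(mcc),
                         threshold=threshold, tp=tp, fp=fp, fn=fn, tn=tn,
                         degenerate=degenerate)


def _collect_fold(
    scores_mat: np.ndarray,
    I_full: np.ndarray,
    test_edges: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool positive (test-edge) and negative (non-edge) scores for a fold."""
    pos = scores_mat[test_edges[:, 0], test_edges[:, 1]]
    test_cols = np.unique(test_edges[:, 1])
    neg_mask = I_full[:, test_cols] == 0
    neg = scores_mat[:, test_cols][neg_mask]
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos), dtype=int),
                             np.zeros(len(neg), dtype=int)])
    return scores, labels


def run_cv(
    net: BipartiteNetwork,
    plan: FoldPlan,
    method: str = "ibnra",
    expression: ExpressionProfileTable | None = None,
    ppi: np.ndarray | None = None,
    config: PredictorConfig = PredictorConfig(),
    baseline_config: BaselineConfig = BaselineConfig(),
    threshold_rule: str = "max_f1",
    leakage_check: bool = True,
    score_fn=None,
) -> EvalReport:
    """Run the cross-validation protocol for one method.

    Per fold the test edges are zeroed out of ``I`` and the model is
    refitted from scratch on the masked matrix.  With ``leakage_check``
    every matrix entering the scorer is asserted to be zero at the
    held-out positions (their support must be contained in the training
    support); the largest observed absolute value is recorded.

    ``score_fn`` (``I_train -> score matrix``) overrides the named method;
    it exists for oracle and null-model experiments.
    """
    I_full = net.I
    E = expression.profiles if expression is not None else None
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    per_fold_auc: list[float] = []
    max_leak = 0.0

    for fold in plan.folds:
        test_edges = plan.edges[fold]
        I_train = I_full.copy()
        I_train[test_edges[:, 0], test_edges[:, 1]] = 0.0
        if I_train.sum() == 0:
            raise ValueError("fold masking removed every training edge")
        if (I_train.sum(axis=1) == 0).any() or (I_train.sum(axis=0) == 0).any():
            logger.warning("fold masking produced zero-degree nodes; "
                           "zero-degree conventions apply")

        if score_fn is not None:
            scores_mat, parts = np.asarray(score_fn(I_train), dtype=float), {"I": I_train}
        else:
            scores_mat, parts = score_matrix(
                I_train, method, ppi, E, config, baseline_config
            )

        if leakage_check:
            r, c = test_edges[:, 0], test_edges[:, 1]
            for name, mat in parts.items():
                leak = float(np.abs(mat[r, c]).max()) if len(r) else 0.0
                max_leak = max(max_leak, leak)
                if leak > 0:
                    raise AssertionError(
                        f"leakage: matrix {name} non-zero at a held-out edge"
                    )

        s, y = _collect_fold(scores_mat, I_full, test_edges)
        all_scores.append(s)
        all_labels.append(y)
        if plan.scheme == "kfold" and y.min() != y.max():
            _, fold_auc = roc_auc(s, y)
            per_fold_auc.append(fold_auc)

    scores = np.concatenate(all_scores)
    labels = np.concatenate(all_labels)
    (fpr, tpr), auc = roc_auc(scores, labels)
    (rec, prec), aupr = pr_aupr(scores, labels)
    report = EvalReport(
        method=method if score_fn is None else "custom",
        scheme=plan.scheme,
        scores=scores, labels=labels, auc=auc, aupr=aupr,
        metrics=binary_metrics(scores, labels, threshold_rule),
        per_fold_auc=per_fold_auc, roc=(fpr, tpr), pr=(rec, prec),
        max_masked_leak=max_leak,
    )
    return report


def alpha_sweep(
    net: BipartiteNetwork,
    plan: FoldPlan,
    alphas,
    expression: ExpressionProfileTable | None = None,
    ppi: np.ndarray | None = None,
    config: PredictorConfig = PredictorConfig(),
) -> list[tuple[float, float]]:
    """Pooled CV AUC of the recommender for each elimination strength.

    The weight matrix does not depend on ``alpha``, so each fold is fitted
    once and only rescored per ``alpha``; at ``alpha = 0`` the result is
    exactly the plain weighted two-round allocation.
    """
    alphas = [float(a) for a in alphas]
    I_full = net.I
    E = expression.profiles if expression is not None else None
    pooled: dict[float, list[np.ndarray]] = {a: [] for a in alphas}
    pooled_labels: list[np.ndarray] = []

    for fold in plan.folds:
        test_edges = plan.edges[fold]
        I_train = I_full.copy()
        I_train[test_edges[:, 0], test_edges[:, 1]] = 0.0
        Sini, W, _ = fit_recommender(I_train, ppi, E, config)
        labels_done = False
        for a in alphas:
            scores_mat = final_scores(eliminate_second_order(W, a), Sini)
            s, y = _collect_fold(scores_mat, I_full, test_edges)
            pooled[a].append(s)
            if not labels_done:
                pooled_labels.append(y)
                labels_done = True

    labels = np.concatenate(pooled_labels)
    out = []
    for a in alphas:
        _, auc = roc_auc(np.concatenate(pooled[a]), labels)
        out.append((a, auc))
    return out
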