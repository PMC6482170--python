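import numpy as np
import pytest

from ibnra.evaluation import (
    binary_metrics,
    make_folds,
    pr_aupr,
    roc_auc,
    run_cv,
)
from ibnra.pipeline import fit_recommender
from ibnra.synthetic import PlantedBlockSpec, generate_network

from conftest import make_net


def pair_count_auc(scores, labels):
    """Brute-force Mann-Whitney AUC: fraction of correctly ordered pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


@pytest.fixture(scope="module")
def small_net():
    net, _ = generate_network(PlantedBlockSpec(
        n_proteins=20, n_lncrnas=40, n_blocks=2, p_in=0.6, p_out=0.05, seed=5))
    return net


class TestMakeFolds:
    def test_even_kfold_split(self, small_net):
        plan = make_folds(small_net, "kfold", k=5, seed=0)
        sizes = [len(f) for f in plan.folds]
        assert sum(sizes) == small_net.n_edges
        assert max(sizes) - min(sizes) <= 1

    def test_loocv_one_edge_per_fold(self, small_net):
        plan = make_folds(small_net, "loocv")
        assert len(plan.folds) == small_net.n_edges
        assert all(len(f) == 1 for f in plan.folds)

    def test_folds_disjoint_and_cover_all_edges(self, small_net):
        plan = make_folds(small_net, "kfold", k=7, seed=3)
        seen = np.concatenate(plan.folds)
        assert len(seen) == len(set(seen)) == small_net.n_edges

    def test_same_seed_reproduces_plan(self, small_net):
        a = make_folds(small_net, "kfold", k=4, seed=9)
        b = make_folds(small_net, "kfold", k=4, seed=9)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa, fb)

    def test_k_larger_than_edge_count_rejected(self, small_net):
        with pytest.raises(ValueError, match="exceeds"):
            make_folds(small_net, "kfold", k=small_net.n_edges + 1)


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_hand_value(self):
        _, auc = roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert auc == pytest.approx(0.75, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_pair_counting_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        scores = np.round(rng.random(n), 1)  # force ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(42)
        scores = rng.standard_normal(100)
        labels = rng.integers(0, 2, 100)
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.exp(scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestPrAupr:
    def test_perfect_ranking(self):
        _, aupr = pr_aupr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert aupr == 1.0

    def test_constant_scores_give_prevalence(self):
        labels = np.array([1, 0, 0, 0, 1])
        _, aupr = pr_aupr(np.full(5, 0.3), labels)
        assert aupr == pytest.approx(labels.mean(), abs=1e-12)

    def test_hand_case_by_threshold_enumeration(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6])
        labels = np.array([1, 0, 1, 0])
        # AP = sum over positives of precision at their recall step:
        # at 0.9: P=1/1 * dR 1/2; at 0.7: P=2/3 * dR 1/2
        _, aupr = pr_aupr(scores, labels)
        assert aupr == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3), abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pr_aupr([0.1, 0.2], [0, 0])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.standard_normal(60)
        labels = rng.integers(0, 2, 60)
        _, a1 = pr_aupr(scores, labels)
        _, a2 = pr_aupr(3 * scores + 2, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestBinaryMetrics:
    def test_perfect_classifier(self):
        m = binary_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert (m.pre, m.sen, m.acc, m.f1, m.mcc) == (1, 1, 1, 1, 1)

    def test_hand_confusion_counts(self):
        # threshold 0.5 gives TP=2, FP=1, FN=1, TN=6
        scores = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.2, 0.1, 0.1, 0.1, 0.1])
        labels = np.array([1, 1, 0, 1, 0, 0, 0, 0, 0, 0])
        m = binary_metrics(scores, labels, "fixed:0.5")
        assert (m.tp, m.fp, m.fn, m.tn) == (2, 1, 1, 6)
        assert m.pre == pytest.approx(2 / 3)
        assert m.sen == pytest.approx(2 / 3)
        assert m.acc == pytest.approx(0.8)
        assert m.f1 == pytest.approx(2 / 3)
        assert m.mcc == pytest.approx(11 / 21)

    def test_all_negative_predictions_flagged(self):
        m = binary_metrics([0.1, 0.2, 0.3], [0, 1, 0], "fixed:0.9")
        assert m.sen == 0.0
        assert "pre" in m.degenerate

    def test_max_f1_beats_fixed_thresholds(self):
        rng = np.random.default_rng(7)
        scores = rng.random(200)
        labels = (scores + 0.3 * rng.standard_normal(200)) > 0.6
        best = binary_metrics(scores, labels, "max_f1")
        for thr in np.linspace(0.05, 0.95, 19):
            fixed = binary_metrics(scores, labels, f"fixed:{thr}")
            assert best.f1 >= fixed.f1 - 1e-12

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="threshold rule"):
            binary_metrics([0.1, 0.9], [0, 1], "banana")


class TestRunCv:
    def test_ground_truth_oracle_scores_give_perfect_auc(self, small_net):
        plan = make_folds(small_net, "kfold", k=5, seed=0)
        report = run_cv(small_net, plan, score_fn=lambda I_train: small_net.I)
        assert report.auc == 1.0
        assert report.aupr == 1.0

    def test_random_scores_are_null(self, small_net):
        plan = make_folds(small_net, "kfold", k=5, seed=0)
        rng = np.random.default_rng(0)
        aucs = [run_cv(small_net, plan,
                       score_fn=lambda I: rng.random(I.shape)).auc
                for _ in range(5)]
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_loocv_tests_every_edge_once(self, small_net):
        plan = make_folds(small_net, "loocv")
        report = run_cv(small_net, plan, score_fn=lambda I_train: small_net.I)
        assert int(report.labels.sum()) == small_net.n_edges

    def test_per_fold_auc_collected_for_kfold(self, planted):
        net, expr, ppi, _ = planted
        plan = make_folds(net, "kfold", k=10, seed=0)
        report = run_cv(net, plan, "ibnra", expr, ppi)
        assert len(report.per_fold_auc) == 10
        assert all(0 <= a <= 1 for a in report.per_fold_auc)

    def test_masked_edges_absent_from_all_model_matrices(self, small_net):
        rng = np.random.default_rng(3)
        edges = np.argwhere(small_net.I == 1)
        held = edges[rng.choice(len(edges), size=len(edges) // 5, replace=False)]
        I_train = small_net.I.copy()
        I_train[held[:, 0], held[:, 1]] = 0.0
        _, _, parts = fit_recommender(I_train)
        for name, mat in parts.items():
            assert np.abs(mat[held[:, 0], held[:, 1]]).max() == 0.0, name

    def test_leakage_guard_reports_zero(self, planted):
        net, expr, ppi, _ = planted
        plan = make_folds(net, "kfold", k=5, seed=2)
        report = run_cv(net, plan, "ibnra", expr, ppi, leakage_check=True)
        assert report.max_masked_leak == 0.0
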