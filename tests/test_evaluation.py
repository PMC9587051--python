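"""Evaluation toolkit: confusion, ROC, bootstrap, Fisher, grouped k-fold."""

import itertools

import numpy as np
import pytest
from scipy.stats import hypergeom

from estrocycle.evaluation import (
    bootstrap_accuracy,
    confusion_matrix,
    evaluate_predictions,
    fisher_exact_comparison,
    grouped_kfold_oos,
    one_vs_rest_roc,
    sens_spec_cutoff,
)
from estrocycle.io import DatasetManifest, ImageRecord
from estrocycle.results import StageProbabilities
from estrocycle.stages import CANONICAL_STAGES


def pairwise_auroc(scores, truth):
    """Independent oracle: P(random positive outscores random negative), ties 1/2."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        truth = list(CANONICAL_STAGES) * 3
        counts, norm = confusion_matrix(truth, truth)
        assert np.array_equal(counts.values, np.eye(4) * 3)
        assert np.allclose(norm.values.sum(axis=1), 1.0)

    def test_single_systematic_error_fills_one_cell(self):
        counts, _ = confusion_matrix(["diestrus"] * 7, ["proestrus"] * 7)
        assert counts.loc["diestrus", "proestrus"] == 7
        assert counts.values.sum() == 7

    def test_order_permutation_invariant(self, rng):
        truth = rng.choice(CANONICAL_STAGES, 60).tolist()
        pred = rng.choice(CANONICAL_STAGES, 60).tolist()
        a, _ = confusion_matrix(truth, pred)
        perm = rng.permutation(60)
        b, _ = confusion_matrix([truth[i] for i in perm], [pred[i] for i in perm])
        assert a.equals(b)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="stage"):
            confusion_matrix(["diestrus"], ["anestrus"])


class TestROC:
    def test_perfect_separation_gives_unit_auroc(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        truth = ["estrus", "estrus", "diestrus", "diestrus"]
        *_, auroc = one_vs_rest_roc(np.array(scores), truth, "estrus")
        assert auroc == 1.0

    def test_score_inversion_antisymmetry(self, rng):
        scores = rng.random(30)
        truth = ["estrus" if v else "diestrus" for v in rng.integers(0, 2, 30)]
        *_, a = one_vs_rest_roc(scores, truth, "estrus")
        *_, b = one_vs_rest_roc(1 - scores, truth, "estrus")
        assert a == pytest.approx(1 - b, abs=1e-12)

    def test_four_sample_hand_case(self):
        # pairs: (0.9 vs 0.8) win, (0.9 vs 0.1) win, (0.4 vs 0.8) loss,
        # (0.4 vs 0.1) win -> 3/4
        scores = np.array([0.9, 0.8, 0.4, 0.1])
        truth = ["estrus", "diestrus", "estrus", "diestrus"]
        *_, auroc = one_vs_rest_roc(scores, truth, "estrus")
        assert auroc == pytest.approx(0.75)

    def test_matches_pairwise_win_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 25))
            scores = np.round(rng.random(n), 2)  # ties likely
            labels = rng.integers(0, 2, n)
            if labels.all() or not labels.any():
                continue
            truth = ["estrus" if v else "diestrus" for v in labels]
            *_, auroc = one_vs_rest_roc(scores, truth, "estrus")
            assert auroc == pytest.approx(pairwise_auroc(scores, labels), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            one_vs_rest_roc(np.array([0.1, 0.2]), ["estrus", "estrus"], "estrus")

    def test_curve_endpoints(self, rng):
        scores = rng.random(40)
        truth = ["estrus" if v else "diestrus" for v in rng.integers(0, 2, 40)]
        fpr, tpr, _, _ = one_vs_rest_roc(scores, truth, "estrus")
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)


class TestSensSpec:
    def test_symmetric_distributions_cross_at_half(self, rng):
        pos = 0.5 + 0.3 * rng.random(500)
        neg = 0.5 - 0.3 * rng.random(500)
        scores = np.concatenate([pos, neg])
        truth = np.concatenate([np.ones(500, bool), np.zeros(500, bool)])
        out = sens_spec_cutoff(scores, truth)
        assert out.crossing == pytest.approx(0.5, abs=0.02)

    def test_grid_endpoint_contract(self, rng):
        scores = rng.random(50)
        truth = rng.integers(0, 2, 50).astype(bool)
        out = sens_spec_cutoff(scores, truth)
        assert out.sensitivity[0] == 1.0  # threshold 0: everything called positive
        assert out.specificity[-1] == 1.0  # threshold 1: nothing called positive

    def test_crossing_matches_dense_grid_minimizer(self, rng):
        scores = rng.random(80)
        truth = scores + rng.normal(0, 0.3, 80) > 0.5
        out = sens_spec_cutoff(scores, truth)
        dense = np.arange(0, 1.0001, 1e-4)
        sens = np.array([(scores[truth] >= t).mean() for t in dense])
        spec = np.array([(scores[~truth] < t).mean() for t in dense])
        best = dense[int(np.argmin(np.abs(sens - spec)))]
        assert abs(out.crossing - best) <= max(1e-4, np.diff(
            np.unique(np.concatenate([[0], np.unique(scores), [1]]))
        ).max())


class TestBootstrap:
    def test_perfect_predictions_degenerate_at_one(self):
        out = bootstrap_accuracy(["estrus"] * 10, ["estrus"] * 10, n_iter=200, seed=0)
        assert np.all(out.accuracies == 1.0)
        assert out.bar_low == out.bar_high == 1.0

    def test_mean_close_to_point_accuracy(self, rng):
        truth = rng.choice(CANONICAL_STAGES, 200).tolist()
        pred = [t if rng.random() < 0.8 else "estrus" for t in truth]
        point = np.mean([t == p for t, p in zip(truth, pred)])
        out = bootstrap_accuracy(truth, pred, n_iter=5000, seed=1)
        mc_se = np.sqrt(point * (1 - point) / 200)
        assert abs(out.mean - point) < 2 * mc_se

    def test_fixed_seed_identical(self):
        truth = ["estrus", "diestrus"] * 10
        pred = ["estrus", "estrus"] * 10
        a = bootstrap_accuracy(truth, pred, n_iter=100, seed=7)
        b = bootstrap_accuracy(truth, pred, n_iter=100, seed=7)
        assert np.array_equal(a.accuracies, b.accuracies)


def enumerate_fisher_p(a, b, c, d):
    """Full hypergeometric enumeration of the two-sided exact test."""
    n1, n2, k = a + b, c + d, a + c
    support = range(max(0, k - n2), min(k, n1) + 1)
    pmf = {x: hypergeom.pmf(x, n1 + n2, n1, k) for x in support}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9)))


class TestFisher:
    def test_identical_groups_are_null(self):
        out = fisher_exact_comparison(5, 10, 5, 10)
        assert out.odds_ratio == pytest.approx(1.0)
        assert out.p_value == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        out = fisher_exact_comparison(10, 10, 0, 10)
        assert out.p_value == pytest.approx(enumerate_fisher_p(10, 0, 0, 10),
                                            rel=1e-9)

    def test_sample_odds_ratio_arithmetic(self):
        out = fisher_exact_comparison(8, 10, 4, 10)
        assert out.odds_ratio == pytest.approx((8 * 6) / (2 * 4))

    def test_swapping_groups_preserves_p(self, rng):
        for _ in range(50):
            n_a, n_b = rng.integers(1, 12, 2)
            ca, cb = rng.integers(0, n_a + 1), rng.integers(0, n_b + 1)
            x = fisher_exact_comparison(ca, n_a, cb, n_b)
            y = fisher_exact_comparison(cb, n_b, ca, n_a)
            assert x.p_value == pytest.approx(y.p_value, rel=1e-12)
            assert 0 < x.p_value <= 1

    def test_woolf_interval_brackets_the_estimate(self):
        out = fisher_exact_comparison(40, 50, 25, 50)
        assert out.ci_low < out.odds_ratio < out.ci_high

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_comparison(0, 0, 1, 2)


class _ProportionTrainer:
    """Cheap stand-in classifier reading the generator's cell proportions."""

    def __call__(self, train_manifest):
        def predict(manifest):
            out = []
            for r in manifest:
                p = r.cell_proportions
                if p.leukocyte_frac > 0.5:
                    out.append("diestrus")
                elif p.cornified_frac > 0.5:
                    out.append("estrus")
                elif p.nucleated_frac > 0.5:
                    out.append("proestrus")
                else:
                    out.append("metestrus")
            return out
        return predict


class TestGroupedKFold:
    @pytest.fixture()
    def manifest(self):
        from estrocycle.synthetic import generate_dataset
        return generate_dataset(18, seed=4, render=False, n_subjects=12)

    def test_subject_folds_never_leak(self, manifest):
        report = grouped_kfold_oos(
            manifest, "subject_id", _ProportionTrainer(), k=6, seed=0
        )
        assert len(report.per_fold_accuracy) == 6
        assert all(len(f) == 2 for f in report.fold_groups)  # 12 subjects / 6 folds
        flat = [g for f in report.fold_groups for g in f]
        assert len(flat) == len(set(flat)) == 12

    def test_leave_one_stain_out_gives_one_eval_per_stain(self):
        from estrocycle.synthetic import generate_dataset
        stains = ("HE", "Shorr", "Giemsa", "CresylViolet", "CrystalViolet")
        m = generate_dataset(10, seed=5, render=False, stains=stains)
        report = grouped_kfold_oos(
            m, "stain", _ProportionTrainer(), mode="leave_one_out"
        )
        assert len(report.per_fold_accuracy) == 5
        assert sorted(g for f in report.fold_groups for g in f) == sorted(stains)

    def test_mean_accuracy_is_average_of_folds(self, manifest):
        report = grouped_kfold_oos(
            manifest, "subject_id", _ProportionTrainer(), k=6, seed=0
        )
        assert report.mean_accuracy == pytest.approx(
            np.mean(report.per_fold_accuracy)
        )

    def test_too_few_groups_suggests_smaller_k(self, manifest):
        with pytest.raises(ValueError, match="k <="):
            grouped_kfold_oos(manifest, "species", _ProportionTrainer(), k=6)


def test_evaluation_report_composes(rng):
    truth = rng.choice(CANONICAL_STAGES, 80).tolist()
    pred = [t if rng.random() < 0.7 else "metestrus" for t in truth]
    scores = []
    for p in pred:
        base = np.full(4, 0.1)
        base[CANONICAL_STAGES.index(p)] = 0.7
        scores.append(StageProbabilities(tuple(base)))
    report = evaluate_predictions(truth, pred, scores, n_boot=200, seed=0)
    assert report.confusion.values.sum() == 80
    assert report.accuracy == pytest.approx(
        np.trace(report.confusion.values) / 80
    )
    assert set(report.auroc) == set(CANONICAL_STAGES)
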