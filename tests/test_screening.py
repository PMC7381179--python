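"""Patient-disjoint splitting, CV screening, Youden thresholds, metrics."""

import numpy as np
import pandas as pd
import pytest

from mepmorph import (
    FeatureMatrix,
    RaterSpec,
    evaluate,
    fit_threshold_youden,
    roc_pr_curves,
    screen_features,
    simulate_rater_labels,
    split_train_test,
    top_k_overlap,
)
from mepmorph.consensus import ConsensusSet, build_consensus
from mepmorph.screening import ScreeningResult, curve_area, rater_operating_point


def _matrix(n_traces=60, n_patients=20, seed=0, features=None):
    rng = np.random.default_rng(seed)
    ids = [f"t{i:03d}" for i in range(n_traces)]
    patients = pd.Series([f"P{i % n_patients:03d}" for i in range(n_traces)], index=ids)
    if features is None:
        features = {"f1": rng.standard_normal(n_traces), "f2": rng.standard_normal(n_traces)}
    return FeatureMatrix(values=pd.DataFrame(features, index=ids), patients=patients)


class TestSplit:
    def test_two_patients_split_one_each(self):
        m = _matrix(n_traces=8, n_patients=2)
        train, test = split_train_test(m, 0.5, seed=1)
        assert set(m.patients.loc[train]) != set(m.patients.loc[test])
        assert len(train) + len(test) == 8

    def test_patient_sets_disjoint(self):
        m = _matrix(n_traces=200, n_patients=50, seed=3)
        for seed in range(5):
            train, test = split_train_test(m, 0.5, seed=seed)
            assert not (set(m.patients.loc[train]) & set(m.patients.loc[test]))

    def test_deterministic(self):
        m = _matrix(n_traces=300, n_patients=100)
        a = split_train_test(m, 0.5, seed=17)
        b = split_train_test(m, 0.5, seed=17)
        assert list(a[0]) == list(b[0]) and list(a[1]) == list(b[1])

    def test_single_patient_rejected(self):
        m = _matrix(n_traces=4, n_patients=1)
        with pytest.raises(ValueError, match="2 patients"):
            split_train_test(m, 0.5, seed=0)


def _labels_from(values, index):
    return ConsensusSet("one_vote", pd.Series(values, index=index, dtype=int), rater="R")


class TestScreenFeatures:
    def test_label_identical_feature_is_perfect(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 120)
        m = _matrix(
            n_traces=120,
            n_patients=40,
            features={"oracle": y.astype(float), "noise": rng.standard_normal(120)},
        )
        res = screen_features(m, _labels_from(y, m.values.index), n_folds=3, seed=0)
        assert res.mean_auc["oracle"] == 1.0
        assert res.ranking[0] == "oracle"

    def test_inverted_feature_also_perfect(self):
        """AUC comes from predicted probability, which re-orients a
        negatively associated feature."""
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 120)
        m = _matrix(n_traces=120, n_patients=40, features={"anti": 1.0 - y})
        res = screen_features(m, _labels_from(y, m.values.index), n_folds=3, seed=0)
        assert res.mean_auc["anti"] == 1.0

    def test_model_auc_equals_oriented_feature_auc_per_fold(self):
        """A 1-D logistic model is monotone in the feature, so its fold
        AUC equals the raw feature's (possibly flipped) fold AUC."""
        from sklearn.metrics import roc_auc_score
        from sklearn.model_selection import GroupKFold

        rng = np.random.default_rng(4)
        n = 150
        x = rng.standard_normal(n)
        y = (x + rng.standard_normal(n) > 0).astype(int)
        m = _matrix(n_traces=n, n_patients=50, features={"x": x})
        res = screen_features(m, _labels_from(y, m.values.index), n_folds=3, seed=9)
        # recompute raw-feature fold AUCs with the same shuffling
        order = np.random.default_rng(9).permutation(n)
        xs, ys = x[order], y[order]
        groups = m.patients.to_numpy()[order]
        raw = []
        for tr_idx, te_idx in GroupKFold(3).split(xs, ys, groups):
            a = roc_auc_score(ys[te_idx], xs[te_idx])
            raw.append(max(a, 1 - a) if roc_auc_score(ys[tr_idx], xs[tr_idx]) < 0.5 else a)
        np.testing.assert_allclose(sorted(res.fold_auc["x"]), sorted(raw), atol=1e-12)

    def test_zero_variance_and_missing_features_absent(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 60)
        feats = {
            "const": np.ones(60),
            "holey": np.where(np.arange(60) == 3, np.nan, rng.standard_normal(60)),
            "ok": rng.standard_normal(60),
        }
        m = _matrix(n_traces=60, n_patients=20, features=feats)
        res = screen_features(m, _labels_from(y, m.values.index), n_folds=3, seed=0)
        assert np.isnan(res.mean_auc["const"])
        assert np.isnan(res.mean_auc["holey"])
        assert res.ranking == ["ok"]

    def test_top_k_overlap(self):
        def mk(ranking):
            return ScreeningResult(
                rater="r",
                mean_auc=pd.Series(dtype=float),
                fold_auc=pd.DataFrame(),
                ranking=ranking,
            )

        a, b = mk(["x", "y", "z"]), mk(["y", "q", "x"])
        assert top_k_overlap([a], k=2) == {"x", "y"}
        assert top_k_overlap([a, b], k=2) == {"y"}
        assert top_k_overlap([a, mk(["p", "q"])], k=2) == set()


class TestYouden:
    def test_perfect_separation_midpoint(self):
        model = fit_threshold_youden([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert model.threshold == pytest.approx(0.5)
        assert model.youden_j == pytest.approx(1.0)
        assert np.array_equal(model.predict([0.3, 0.7]), [0, 1])

    def test_null_scores_have_small_j(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=2000)
        labels = rng.integers(0, 2, 2000)
        model = fit_threshold_youden(scores, labels)
        assert model.youden_j <= 0.1

    def test_recovers_simulated_rater_thresholds(self):
        """Per-rater Youden cuts on the latent score recover each rater's
        true threshold within 0.05, in the right order."""
        taus = (0.40, 0.45, 0.50, 0.55, 0.60)
        rng = np.random.default_rng(10)
        z = rng.uniform(0, 1, 500)
        raters = [RaterSpec(f"N{i+1}", t, 0.05, 0.0, 0.0) for i, t in enumerate(taus)]
        table = simulate_rater_labels(z, raters, rng_seed=77)
        z_by_id = pd.Series(z, index=[f"t{i:05d}" for i in range(len(z))])
        recovered = []
        for r in raters:
            one = build_consensus(table, "one_vote", rater=r.rater_id)
            scores = z_by_id.loc[one.labels.index]
            model = fit_threshold_youden(scores.to_numpy(), one.labels.to_numpy())
            recovered.append(model.threshold)
        for got, true in zip(recovered, taus):
            assert abs(got - true) <= 0.05
        assert recovered == sorted(recovered)

    def test_youden_maximises_balanced_accuracy(self):
        """The Youden threshold's balanced accuracy matches the best over
        an exhaustive sweep of candidate thresholds."""
        rng = np.random.default_rng(6)
        x = rng.standard_normal(300)
        y = (x + rng.standard_normal(300) * 0.8 > 0.2).astype(int)
        model = fit_threshold_youden(x, y)

        def balanced_acc(t):
            pred = x > t
            tpr = (pred & (y == 1)).sum() / (y == 1).sum()
            tnr = (~pred & (y == 0)).sum() / (y == 0).sum()
            return (tpr + tnr) / 2

        uniq = np.unique(x)
        sweep = max(balanced_acc(t) for t in (uniq[:-1] + uniq[1:]) / 2)
        assert balanced_acc(model.threshold) == pytest.approx(sweep, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_threshold_youden([0.1, 0.2], [1, 1])


class TestEvaluate:
    def _six_points(self):
        ids = [f"t{i}" for i in range(6)]
        scores = pd.Series([1.0, 2, 3, 4, 5, 6], index=ids)
        truth = ConsensusSet("five_vote", pd.Series([0, 0, 1, 0, 1, 1], index=ids))
        return scores, truth

    def test_six_point_auc_is_eight_ninths(self):
        """Brute force over the 9 (pos, neg) pairs: 8 concordant, 0 ties."""
        scores, truth = self._six_points()
        m = evaluate(scores, (scores > 3.5).astype(int), truth)
        assert m["auc"] == pytest.approx(8 / 9, abs=1e-12)

    def test_f1_from_table3_precision_recall(self):
        """F1 = 2pr/(p+r): precision 0.84 and recall 0.78 give 0.81."""
        f1 = 2 * 0.84 * 0.78 / (0.84 + 0.78)
        assert f1 == pytest.approx(0.8089, abs=5e-4)
        assert round(f1, 2) == 0.81

    def test_perfect_predictions_all_ones(self):
        ids = [f"t{i}" for i in range(40)]
        y = pd.Series(np.random.default_rng(0).integers(0, 2, 40), index=ids)
        truth = ConsensusSet("five_vote", y)
        m = evaluate(y.astype(float), y, truth)
        for key in ("f1", "accuracy", "precision", "recall", "kappa", "auc"):
            assert m[key] == 1.0

    def test_three_vote_list_reports_mean_and_std(self):
        ids = [f"t{i}" for i in range(30)]
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.uniform(size=30), index=ids)
        pred = (scores > 0.5).astype(int)
        sets = [
            ConsensusSet("three_vote", pd.Series(rng.integers(0, 2, 30), index=ids),
                         target_rater="N1", left_out=f"N{i}")
            for i in (2, 3, 4, 5)
        ]
        m = evaluate(scores, pred, sets)
        assert m["n_sets"] == 4
        singles = [evaluate(scores, pred, s)["accuracy"] for s in sets]
        assert m["accuracy"] == pytest.approx(np.mean(singles), abs=1e-12)
        assert m["accuracy_std"] == pytest.approx(np.std(singles), abs=1e-12)


class TestCurves:
    def test_perfect_scores_pass_through_corner(self):
        ids = [f"t{i}" for i in range(20)]
        y = pd.Series([0] * 10 + [1] * 10, index=ids)
        roc, pr = roc_pr_curves(pd.Series(np.arange(20.0), index=ids), ConsensusSet("five_vote", y))
        assert ((roc["fpr"] == 0.0) & (roc["tpr"] == 1.0)).any()

    def test_random_scores_area_near_half(self):
        rng = np.random.default_rng(0)
        ids = [f"t{i}" for i in range(5000)]
        scores = pd.Series(rng.uniform(size=5000), index=ids)
        y = pd.Series(rng.integers(0, 2, 5000), index=ids)
        roc, _ = roc_pr_curves(scores, ConsensusSet("five_vote", y))
        assert abs(curve_area(roc) - 0.5) <= 0.03

    def test_curve_area_equals_scalar_auc(self):
        rng = np.random.default_rng(8)
        ids = [f"t{i}" for i in range(500)]
        scores = pd.Series(rng.standard_normal(500), index=ids)
        y = pd.Series((scores.to_numpy() + rng.standard_normal(500) > 0).astype(int), index=ids)
        truth = ConsensusSet("five_vote", y)
        m = evaluate(scores, (scores > 0).astype(int), truth)
        roc, _ = roc_pr_curves(scores, truth)
        assert abs(curve_area(roc) - m["auc"]) <= 1e-12

    def test_auc_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(2)
        ids = [f"t{i}" for i in range(300)]
        scores = pd.Series(rng.standard_normal(300), index=ids)
        y = pd.Series((scores.to_numpy() > 0.3).astype(int), index=ids)
        truth = ConsensusSet("five_vote", y)
        base = evaluate(scores, y, truth)["auc"]
        for transform in (np.exp, lambda s: pd.Series(s).rank().to_numpy()):
            t_scores = pd.Series(np.asarray(transform(scores.to_numpy())), index=ids)
            assert evaluate(t_scores, y, truth)["auc"] == pytest.approx(base, abs=1e-12)

    def test_rater_operating_point_on_perfect_rater(self):
        ids = [f"t{i}" for i in range(10)]
        y = pd.Series([0, 1] * 5, index=ids)
        pt = rater_operating_point(y, ConsensusSet("five_vote", y))
        assert pt["tpr"] == 1.0 and pt["fpr"] == 0.0 and pt["precision"] == 1.0
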