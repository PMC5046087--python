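"""Differential testing, imputation rules, SVM classifier, evaluation."""

import numpy as np
import pandas as pd
import pytest

import cemsnorm as cn
from cemsnorm import biomarkers
from conftest import make_matrix


def bh_bruteforce(p):
    """Step-up definition: adj p_(i) = min_{j >= i} m * p_(j) / j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    adj_sorted = np.array([
        min(min(m * ranked[j] / (j + 1) for j in range(i, m)), 1.0)
        for i in range(m)])
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def auc_exhaustive(scores_pos, scores_neg):
    """Concordant-pair count with half credit for ties."""
    total = 0.0
    for a in scores_pos:
        for b in scores_neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(scores_pos) * len(scores_neg))


class TestGroupPresenceFilter:
    def test_requires_fraction_in_both_groups(self):
        x = np.full((2, 9), 1.0)
        x[0, 5:8] = np.nan          # group B: 1/4 present -> drop
        x[1, 8] = np.nan            # 80%/75% -> keep
        fm = make_matrix(x, groups=["A"] * 5 + ["B"] * 4)
        out = cn.group_presence_filter(fm, min_frac=0.75)
        assert list(out.feature_ids) == [fm.feature_ids[1]]

    def test_exact_threshold_kept(self):
        x = np.full((1, 8), 2.0)
        x[0, 0] = np.nan            # 3/4 = 75% in group A
        x[0, 4] = np.nan            # 3/4 = 75% in group B
        fm = make_matrix(x, groups=["A"] * 4 + ["B"] * 4)
        assert cn.group_presence_filter(fm, 0.75).n_features == 1

    def test_is_intersection_of_per_group_filters(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(1, 5, size=(40, 12))
        x[rng.random(x.shape) < 0.3] = np.nan
        groups = ["A"] * 6 + ["B"] * 6
        fm = make_matrix(x, groups=groups)
        both = set(cn.group_presence_filter(fm, 0.5).feature_ids)
        per_group = []
        for cols in (range(6), range(6, 12)):
            sub = fm.values.iloc[:, list(cols)]
            per_group.append(set(sub.index[
                sub.notna().mean(axis=1) >= 0.5]))
        assert both == per_group[0] & per_group[1]


class TestImpute:
    def test_discovery_fills_group_mean(self):
        x = np.array([[2.0, np.nan, 4.0, 7.0, 7.0, np.nan]])
        fm = make_matrix(x, groups=["U", "U", "U", "H", "H", "H"])
        out = cn.impute_missing(fm, mode="discovery")
        assert out.values.iloc[0, 1] == 3.0   # mean of (2, 4)
        assert out.values.iloc[0, 5] == 7.0

    def test_validation_uses_discovery_overall_mean(self):
        x = np.array([[np.nan, 1.0]])
        fm = make_matrix(x)
        means = pd.Series({fm.feature_ids[0]: 5.5})
        out = cn.impute_missing(fm, mode="validation",
                                discovery_means=means)
        assert out.values.iloc[0, 0] == 5.5

    def test_no_missing_is_identity(self):
        x = np.arange(1.0, 13.0).reshape(3, 4)
        fm = make_matrix(x, groups=["A", "A", "B", "B"])
        out = cn.impute_missing(fm, mode="discovery")
        np.testing.assert_array_equal(out.values.to_numpy(), x)

    def test_group_entirely_missing_rejected(self):
        x = np.array([[1.0, 2.0, np.nan, np.nan]])
        fm = make_matrix(x, groups=["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="entirely missing"):
            cn.impute_missing(fm, mode="discovery")


class TestWilcoxonBh:
    def test_identical_distributions_not_significant(self):
        x = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (3, 2))
        fm = make_matrix(x, groups=["A"] * 4 + ["B"] * 4)
        out = cn.wilcoxon_bh(fm)
        assert (out["p_value"] > 0.9).all()
        assert not out["significant"].any()

    def test_constant_feature_p_one(self):
        x = np.full((1, 6), 3.0)
        fm = make_matrix(x, groups=["A"] * 3 + ["B"] * 3)
        assert cn.wilcoxon_bh(fm)["p_value"].iloc[0] == 1.0

    def test_bh_monotone_example(self):
        adj = bh_bruteforce([0.01, 0.02, 0.03])
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])
        from statsmodels.stats.multitest import multipletests
        np.testing.assert_allclose(
            multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1], adj)

    def test_bh_matches_bruteforce_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(13)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(
                multipletests(p, method="fdr_bh")[1], bh_bruteforce(p),
                atol=1e-12)

    def test_fold_change_sign_follows_positive_group(self):
        rng = np.random.default_rng(14)
        a = rng.normal(8, 0.1, size=(1, 10))   # control
        b = rng.normal(16, 0.1, size=(1, 10))  # disease, 2x up
        fm = make_matrix(np.hstack([a, b]),
                         groups=["control"] * 10 + ["disease"] * 10)
        out = cn.wilcoxon_bh(fm, positive_label="disease")
        assert out["log2_fold_change"].iloc[0] == pytest.approx(1.0,
                                                                abs=0.05)


class TestClassifier:
    def _separated(self, seed=0, n=10, p=8, delta=5.0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(p, n))
        b = rng.normal(delta, 1, size=(p, n))
        return make_matrix(np.hstack([a, b]) + 20,
                           groups=["control"] * n + ["disease"] * n)

    def test_well_separated_classes_loo_perfect(self):
        fm = self._separated()
        correct = 0
        for held in fm.sample_ids:
            rest = [s for s in fm.sample_ids if s != held]
            model = cn.train_classifier(fm.subset_samples(rest), "disease")
            pred = cn.score_samples(model, fm.subset_samples([held]))
            correct += (pred["predicted"].iloc[0]
                        == fm.groups[held])
        assert correct == fm.n_samples

    def test_permuted_labels_near_chance_on_held_out_samples(self):
        """Training on permuted labels must not beat chance on a balanced
        held-out set. (Leave-one-out is not used here: with a null model it
        is biased far *below* chance, because the held-out sample's class
        is always the training minority.)"""
        accs = []
        for seed in range(40):
            rng = np.random.default_rng(100 + seed)
            train = self._separated(seed=seed, n=8, p=5, delta=5.0)
            perm = rng.permutation(train.groups.to_numpy())
            train = cn.FeatureMatrix(train.values,
                                     groups=pd.Series(perm,
                                                      index=train.sample_ids))
            test = self._separated(seed=1000 + seed, n=8, p=5, delta=5.0)
            model = cn.train_classifier(train, "disease")
            pred = cn.score_samples(model, test)
            accs.append((pred["predicted"].to_numpy()
                         == test.groups.to_numpy()).mean())
        assert abs(np.mean(accs) - 0.5) <= 0.15

    def test_json_round_trip_reproduces_scores_exactly(self):
        fm = self._separated(seed=3)
        model = cn.train_classifier(fm, "disease")
        s1 = cn.score_samples(model, fm)
        back = biomarkers.ClassifierModel.from_dict(model.to_dict())
        s2 = cn.score_samples(back, fm)
        np.testing.assert_array_equal(s1["score"].to_numpy(),
                                      s2["score"].to_numpy())

    def test_agreement_with_sklearn_decision_function(self):
        from sklearn.svm import SVC
        fm = self._separated(seed=4)
        model = cn.train_classifier(fm, "disease")
        X = fm.values.to_numpy().T
        Xs = (X - model.standardize_mean) / model.standardize_sd
        y = (fm.groups == "disease").astype(int).to_numpy()
        svc = SVC(C=1.0, gamma=0.03125, kernel="rbf").fit(Xs, y)
        np.testing.assert_allclose(model.decision_function(Xs),
                                   svc.decision_function(Xs), atol=1e-10)

    def test_single_class_rejected(self):
        fm = make_matrix(np.random.default_rng(0).normal(size=(3, 4)) + 10,
                         groups=["A"] * 4)
        with pytest.raises(ValueError, match="two classes"):
            cn.train_classifier(fm, "A")

    def test_score_threshold_strictly_positive_means_disease(self):
        labels = np.where(np.array([1.2, -0.3, 0.0]) > 0, "disease",
                          "control")
        assert list(labels) == ["disease", "control", "control"]


class TestEvaluate:
    def _pred(self, scores, labels, ids=None):
        ids = ids or [f"v{i}" for i in range(len(scores))]
        return pd.DataFrame({"score": scores,
                             "predicted": ["disease" if s > 0 else "control"
                                           for s in scores]}, index=ids)

    def test_reported_confusion_counts_give_reported_rates(self):
        # 13 of 17 positives and 6 of 7 negatives correct
        scores = [1.0] * 13 + [-1.0] * 4 + [-1.0] * 6 + [1.0]
        truth = pd.Series(["disease"] * 17 + ["control"] * 7,
                          index=[f"v{i}" for i in range(24)])
        out = cn.evaluate_predictions(self._pred(scores, truth), truth,
                                      positive_label="disease")
        assert out["sensitivity_percent"] == 76.5
        assert out["specificity_percent"] == 85.7

    def test_perfect_separation(self):
        scores = [2.0, 1.0, -1.0, -2.0]
        truth = pd.Series(["disease", "disease", "control", "control"],
                          index=[f"v{i}" for i in range(4)])
        out = cn.evaluate_predictions(self._pred(scores, truth), truth,
                                      positive_label="disease")
        assert out["auc"] == 1.0
        assert out["sensitivity_percent"] == 100.0
        assert out["specificity_percent"] == 100.0

    def test_auc_matches_exhaustive_pairs(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            n_pos = int(rng.integers(2, 15))
            n_neg = int(rng.integers(2, 15))
            pos = np.round(rng.normal(0.5, 1, n_pos), 1)  # rounding -> ties
            neg = np.round(rng.normal(0.0, 1, n_neg), 1)
            assert cn.auc_rank(pos, neg) == pytest.approx(
                auc_exhaustive(pos, neg), abs=1e-12)

    def test_single_class_truth_rejected(self):
        truth = pd.Series(["disease", "disease"], index=["v0", "v1"])
        with pytest.raises(ValueError):
            cn.evaluate_predictions(self._pred([1.0, -1.0], truth), truth,
                                    positive_label="disease")


def test_differential_pipeline_recovers_planted_effects():
    """Presence filter -> impute -> rank-sum/BH -> SVM on a cohort with 30
    planted two-fold features; blinded validation scored with the frozen
    model."""
    cfg = cn.SimulationConfig(m=200, n_control=15 + 7, n_disease=34 + 17,
                              warp_family="none", seed=31)
    co = cn.generate_cohort(cfg)
    groups = co.matrix.groups
    # dilution is removed by stable-standard normalization before testing
    ss = cn.select_stable_features(co.matrix, n_candidates=60)
    norm = cn.FeatureMatrix(2.0 ** cn.normalize_matrix(co.matrix.log2(),
                                                       ss.features),
                            groups=groups)
    ctrl = [s for s in norm.sample_ids if groups[s] == "control"]
    dis = [s for s in norm.sample_ids if groups[s] == "disease"]
    disc = norm.subset_samples(ctrl[:15] + dis[:34])
    valid = norm.subset_samples(ctrl[15:] + dis[34:])

    filtered = cn.group_presence_filter(disc, 0.75)
    imputed = cn.impute_missing(filtered, mode="discovery")
    diff = cn.wilcoxon_bh(imputed, positive_label="disease")
    sig = list(diff.index[diff["significant"]])
    rec = cn.truth_metrics(co.truth, differential_predicted=sig)
    assert rec["differential"]["recall"] >= 0.8

    model = cn.train_classifier(imputed.subset_features(sig), "disease")
    vimp = cn.impute_missing(
        cn.FeatureMatrix(valid.values.reindex(sig), groups=valid.groups),
        mode="validation", discovery_means=model.imputation_means)
    scored = cn.score_samples(model, vimp)
    out = cn.evaluate_predictions(scored, valid.groups, "disease",
                                  n_bootstrap=200, seed=0)
    assert out["auc"] >= 0.85
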