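"""Differential analysis and SVM biomarker classification.

Discovery workflow: presence filter (>=75% detected in each group),
group-mean imputation, two-sided Wilcoxon rank-sum tests with
Benjamini-Hochberg adjustment (significant at adjusted p < 0.05), then an
RBF-kernel SVM (C = 1, gamma = 0.03125) on the standardized significant
features. A decision score > 0 predicts disease. Validation samples are
imputed with the discovery-wide feature means and scored with the frozen
model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .datatypes import FeatureMatrix

log = logging.getLogger(__name__)

SVM_C = 1.0
SVM_GAMMA = 0.03125
BH_ALPHA = 0.05
#: exact rank-sum distribution only when both groups are at most this large
EXACT_WILCOXON_MAX_N = 20


def group_presence_filter(fm: FeatureMatrix,
                          min_frac: float = 0.75) -> FeatureMatrix:
    """Keep features detected in >= min_frac of the samples of BOTH groups."""
    cols = fm.group_columns()
    if len(cols) != 2:
        raise ValueError("need exactly two groups")
    keep = pd.Series(True, index=fm.feature_ids)
    for ids in cols.values():
        frac = fm.values[ids].notna().mean(axis=1)
        keep &= frac >= min_frac
    if not keep.any():
        raise ValueError("presence filter removed every feature")
    return fm.subset_features(list(keep[keep].index))


def impute_missing(fm: FeatureMatrix, mode: str = "discovery",
                   discovery_means: Optional[pd.Series] = None
                   ) -> FeatureMatrix:
    """Fill missing intensities.

    ``discovery``: per-feature mean of the observed values in the sample's
    own group. ``validation``: per-feature mean over all discovery samples
    (post-imputation; see ``discovery_overall_means``), independent of the
    unknown group of the new sample.
    """
    x = fm.values.copy()
    if mode == "discovery":
        for ids in fm.group_columns().values():
            sub = x[ids]
            means = sub.mean(axis=1, skipna=True)
            bad = sub.isna().all(axis=1)
            if bad.any():
                raise ValueError(
                    f"features entirely missing in one group: "
                    f"{list(bad[bad].index)[:5]} (apply the presence filter)")
            x[ids] = sub.apply(lambda row: row.fillna(means[row.name]), axis=1)
    elif mode == "validation":
        if discovery_means is None:
            raise ValueError("validation mode requires discovery_means")
        means = discovery_means.reindex(x.index)
        if means.isna().any():
            raise ValueError("discovery_means missing for some features")
        x = x.apply(lambda row: row.fillna(means[row.name]), axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return FeatureMatrix(x, groups=fm.groups)


def discovery_overall_means(imputed: FeatureMatrix) -> pd.Series:
    """Per-feature mean over all discovery samples after imputation."""
    return imputed.values.mean(axis=1)


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if max(len(a), len(b)) <= EXACT_WILCOXON_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"  # tie-corrected normal approximation
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def wilcoxon_bh(fm: FeatureMatrix, positive_label: Optional[str] = None,
                alpha: float = BH_ALPHA) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per feature + Benjamini-Hochberg.

    Returns a DataFrame with raw p, BH-adjusted p, log2 fold change of the
    positive (disease) group's mean over the other group's, and the
    significance flag (adjusted p < alpha). Expects an imputed (complete)
    matrix with two groups of >=2 samples each.
    """
    cols = fm.group_columns()
    if len(cols) != 2:
        raise ValueError("need exactly two groups")
    labels = sorted(cols)
    if positive_label is None:
        positive_label = labels[1]
    if positive_label not in cols:
        raise ValueError(f"{positive_label!r} not among groups {labels}")
    negative_label = [l for l in labels if l != positive_label][0]
    a_cols, b_cols = cols[positive_label], cols[negative_label]
    if min(len(a_cols), len(b_cols)) < 2:
        raise ValueError("each group needs >=2 samples")
    if fm.values.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")

    pvals, lfc = [], []
    for fid in fm.feature_ids:
        a = fm.values.loc[fid, a_cols].to_numpy()
        b = fm.values.loc[fid, b_cols].to_numpy()
        pvals.append(_rank_sum_p(a, b))
        lfc.append(np.log2(a.mean() / b.mean())
                   if a.mean() > 0 and b.mean() > 0 else np.nan)
    adj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "p_value": pvals,
        "p_adjusted": adj,
        "log2_fold_change": lfc,
        "significant": adj < alpha,
    }, index=fm.feature_ids)


@dataclass
class ClassifierModel:
    """Frozen RBF-SVM biomarker classifier; score > 0 predicts disease.

    Stores everything needed for standalone scoring: the biomarker feature
    ids, discovery imputation means, per-feature standardization, and the
    SVM's support vectors / dual coefficients / intercept.
    """
    feature_ids: list[str]
    imputation_means: pd.Series
    standardize_mean: np.ndarray
    standardize_sd: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float = SVM_GAMMA
    C: float = SVM_C
    positive_label: str = "disease"
    negative_label: str = "control"

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """RBF decision values for standardized sample rows X."""
        sq = (np.sum(X ** 2, axis=1)[:, None]
              + np.sum(self.support_vectors ** 2, axis=1)[None, :]
              - 2.0 * X @ self.support_vectors.T)
        K = np.exp(-self.gamma * np.maximum(sq, 0.0))
        return K @ self.dual_coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "feature_ids": self.feature_ids,
            "imputation_means": self.imputation_means.tolist(),
            "standardize_mean": self.standardize_mean.tolist(),
            "standardize_sd": self.standardize_sd.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
            "C": self.C,
            "positive_label": self.positive_label,
            "negative_label": self.negative_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierModel":
        return cls(
            feature_ids=list(d["feature_ids"]),
            imputation_means=pd.Series(d["imputation_means"],
                                       index=d["feature_ids"]),
            standardize_mean=np.asarray(d["standardize_mean"], dtype=float),
            standardize_sd=np.asarray(d["standardize_sd"], dtype=float),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            gamma=float(d["gamma"]),
            C=float(d["C"]),
            positive_label=d["positive_label"],
            negative_label=d["negative_label"],
        )


def train_classifier(fm: FeatureMatrix, positive_label: str,
                     imputation_means: Optional[pd.Series] = None,
                     C: float = SVM_C, gamma: float = SVM_GAMMA
                     ) -> ClassifierModel:
    """Fit the RBF-SVM on a complete, feature-restricted discovery matrix.

    Features are standardized with the training mean/sd. ``imputation_means``
    default to the discovery-wide feature means of ``fm`` and are stored for
    validation-mode imputation at scoring time.
    """
    if fm.groups is None:
        raise ValueError("matrix needs group labels")
    labels = sorted(set(map(str, fm.groups)))
    if len(labels) != 2:
        raise ValueError(f"need exactly two classes, got {labels}")
    if fm.values.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")
    negative_label = [l for l in labels if l != positive_label][0]

    X = fm.values.to_numpy().T  # samples x features
    y = (fm.groups.astype(str) == positive_label).to_numpy().astype(int)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd

    svc = SVC(C=C, gamma=gamma, kernel="rbf")
    svc.fit(Xs, y)
    # sklearn orients decision_function so positive values favor classes_[1];
    # y is 0/1 so classes_[1] == 1 == disease
    return ClassifierModel(
        feature_ids=list(fm.feature_ids),
        imputation_means=(imputation_means.reindex(fm.feature_ids)
                          if imputation_means is not None
                          else fm.values.mean(axis=1)),
        standardize_mean=mu,
        standardize_sd=sd,
        support_vectors=svc.support_vectors_,
        dual_coef=svc.dual_coef_.ravel(),
        intercept=float(svc.intercept_[0]),
        gamma=gamma,
        C=C,
        positive_label=positive_label,
        negative_label=negative_label,
    )


def score_samples(model: ClassifierModel, fm: FeatureMatrix) -> pd.DataFrame:
    """Score samples with a frozen model; label = disease iff score > 0.

    Missing biomarker values (including features absent from ``fm``
    entirely, with a warning) are imputed with the stored discovery means.
    """
    x = fm.values.reindex(model.feature_ids)
    absent = x.isna().all(axis=1)
    if absent.any():
        log.warning("%d model features absent from input; imputing",
                    int(absent.sum()))
    x = x.apply(lambda row: row.fillna(model.imputation_means[row.name]),
                axis=1)
    X = x.to_numpy().T
    Xs = (X - model.standardize_mean) / model.standardize_sd
    scores = model.decision_function(Xs)
    return pd.DataFrame({
        "score": scores,
        "predicted": np.where(scores > 0, model.positive_label,
                              model.negative_label),
    }, index=fm.sample_ids)


def auc_rank(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC: concordant pair fraction, ties 1/2."""
    all_scores = np.concatenate([scores_pos, scores_neg])
    ranks = stats.rankdata(all_scores)
    n_pos, n_neg = len(scores_pos), len(scores_neg)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_predictions(pred: pd.DataFrame, truth: pd.Series,
                         positive_label: str,
                         n_bootstrap: int = 2000,
                         seed: int = 0) -> dict:
    """Confusion counts, sensitivity/specificity (%, one decimal), and
    rank-based AUC with a percentile-bootstrap 95% CI.

    ``pred`` is the score_samples output (columns score, predicted);
    ``truth`` maps sample id -> true label.
    """
    truth = truth.reindex(pred.index).astype(str)
    if truth.isna().any():
        raise ValueError("truth labels missing for some scored samples")
    is_pos = (truth == positive_label).to_numpy()
    if is_pos.all() or not is_pos.any():
        raise ValueError("need at least one positive and one negative truth")
    pred_pos = (pred["predicted"].astype(str) == positive_label).to_numpy()
    tp = int(np.sum(pred_pos & is_pos))
    fn = int(np.sum(~pred_pos & is_pos))
    tn = int(np.sum(~pred_pos & ~is_pos))
    fp = int(np.sum(pred_pos & ~is_pos))
    sensitivity = round(100.0 * tp / (tp + fn), 1)
    specificity = round(100.0 * tn / (tn + fp), 1)

    scores = pred["score"].to_numpy()
    auc = auc_rank(scores[is_pos], scores[~is_pos])
    rng = np.random.default_rng(seed)
    boots = []
    pos_idx, neg_idx = np.where(is_pos)[0], np.where(~is_pos)[0]
    for _ in range(n_bootstrap):
        bp = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        bn = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        boots.append(auc_rank(scores[bp], scores[bn]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
        "sensitivity_percent": sensitivity,
        "specificity_percent": specificity,
        "auc": auc,
        "auc_ci95": (float(lo), float(hi)),
    }
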