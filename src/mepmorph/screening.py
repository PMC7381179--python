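"""Feature screening, threshold selection and classifier evaluation.

The search for a morphology proxy is deliberately one-dimensional: each
candidate feature is fitted alone in a logistic regression against each
individual rater's labels (1-votes), ranked by patient-grouped 3-fold
cross-validated AUC, and the per-rater top-k lists are intersected.  A
feature every rater's labels agree on (in this pipeline, normalised
ApEn) becomes the proxy.  With one predictor the logistic model is a
monotone function of the feature, so classification reduces to a
threshold on the feature scale; the operating threshold is chosen by
the Youden index (maximal TPR - FPR) on the training set, and the
implied per-rater thresholds expose how annotators differ mainly in
their cut-point, not their concept.

Patient-level splitting is used everywhere (train/test and CV folds) so
no patient's traces leak across a split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    auc as curve_auc,
    average_precision_score,
    f1_score,
    precision_recall_curve,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import GroupKFold

from .agreement import cohens_kappa
from .consensus import ConsensusSet

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "ScreeningResult",
    "ThresholdModel",
    "split_train_test",
    "screen_features",
    "top_k_overlap",
    "fit_threshold_youden",
    "evaluate",
    "roc_pr_curves",
    "rater_operating_point",
]


@dataclass
class FeatureMatrix:
    """Traces x named scalar features, with patient grouping for splits."""

    values: pd.DataFrame = field(repr=False)  # index: trace_id, columns: features
    patients: pd.Series = field(repr=False)  # index: trace_id -> patient_id

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicated trace_id in feature matrix")
        missing = self.values.index.difference(self.patients.index)
        if len(missing):
            raise ValueError(f"traces without patient_id: {list(missing)[:5]}")
        self.patients = self.patients.reindex(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, trace_ids) -> "FeatureMatrix":
        return FeatureMatrix(self.values.loc[trace_ids], self.patients.loc[trace_ids])


@dataclass
class ScreeningResult:
    """Per-feature CV AUCs for one rater's labels, plus the ranking."""

    rater: str
    mean_auc: pd.Series  # feature -> mean CV AUC (NaN = not rankable)
    fold_auc: pd.DataFrame = field(repr=False)  # folds x features
    ranking: list[str] = field(default_factory=list)

    def top_k(self, k: int = 10) -> list[str]:
        return self.ranking[:k]


@dataclass
class ThresholdModel:
    """A one-feature classifier: logistic fit plus a decision threshold.

    ``threshold`` lives on the raw feature scale; ``implied_threshold``
    is the logistic model's probability-0.5 point (-intercept/slope),
    which is how a rater's personal cut-point is read off a fit to that
    rater's labels.
    """

    feature: str
    slope: float
    intercept: float
    threshold: float
    youden_j: float
    in_range: bool = True
    seed: Optional[int] = None

    @property
    def implied_threshold(self) -> float:
        if self.slope == 0:
            return float("nan")
        return -self.intercept / self.slope

    def predict(self, scores) -> np.ndarray:
        return (np.asarray(scores, dtype=float) > self.threshold).astype(int)


def split_train_test(
    matrix: FeatureMatrix, fraction: float = 0.5, seed: int = 0
) -> tuple[pd.Index, pd.Index]:
    """Patient-disjoint train/test split of the traces.

    Patients are shuffled and assigned to the training side until its
    trace share reaches ``fraction``; no patient appears on both sides.
    """
    patients = matrix.patients
    unique = np.array(sorted(patients.unique()))
    if unique.size < 2:
        raise ValueError("patient-disjoint split needs at least 2 patients")
    rng = np.random.default_rng(seed)
    order = rng.permutation(unique)
    counts = patients.value_counts()
    target = fraction * len(patients)
    train_patients: set = set()
    n_train = 0
    for p in order:
        if n_train >= target:
            break
        train_patients.add(p)
        n_train += int(counts[p])
    if len(train_patients) == unique.size:  # keep the test side nonempty
        train_patients.discard(order[-1])
        n_train -= int(counts[order[-1]])
    achieved = n_train / len(patients)
    if abs(achieved - fraction) > 0.1 * max(fraction, 1e-9):
        logger.warning("achieved train fraction %.3f deviates from target %.3f", achieved, fraction)
    else:
        logger.info("train fraction %.3f (target %.3f)", achieved, fraction)
    mask = patients.isin(train_patients)
    return matrix.values.index[mask], matrix.values.index[~mask]


def _fold_auc(x: np.ndarray, y: np.ndarray, groups: np.ndarray, n_folds: int, seed: int):
    """Per-fold held-out AUCs of a one-feature logistic regression."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    x, y, groups = x[order], y[order], groups[order]
    aucs = []
    for train_idx, test_idx in GroupKFold(n_splits=n_folds).split(x, y, groups):
        y_tr, y_te = y[train_idx], y[test_idx]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            logger.warning("skipping a CV fold with a single class")
            aucs.append(np.nan)
            continue
        x_tr = x[train_idx]
        mu, sd = x_tr.mean(), x_tr.std()
        sd = sd if sd > 0 else 1.0
        model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=200)
        model.fit(((x_tr - mu) / sd).reshape(-1, 1), y_tr)
        prob = model.predict_proba(((x[test_idx] - mu) / sd).reshape(-1, 1))[:, 1]
        aucs.append(roc_auc_score(y_te, prob))
    return aucs


def screen_features(
    matrix: FeatureMatrix,
    labels: ConsensusSet,
    n_folds: int = 3,
    seed: int = 0,
) -> ScreeningResult:
    """Rank every feature by patient-grouped CV AUC against one label set.

    Each feature is standardised on the fold-train portion, fitted alone
    by unpenalised maximum-likelihood logistic regression, and scored on
    the held-out fold by predicted probability.  Features with missing
    values or zero variance are recorded as absent (NaN) rather than
    ranked.  Ties in mean AUC are broken by feature name.
    """
    common = matrix.values.index.intersection(labels.labels.index)
    if len(common) == 0:
        raise ValueError("no overlap between feature matrix and label set")
    y = labels.labels.loc[common].to_numpy()
    groups = matrix.patients.loc[common].to_numpy()
    fold_rows: dict[str, list] = {}
    means: dict[str, float] = {}
    for name in matrix.feature_names:
        col = matrix.values.loc[common, name].to_numpy(dtype=float)
        if np.isnan(col).any() or np.std(col) == 0:
            means[name] = np.nan
            fold_rows[name] = [np.nan] * n_folds
            continue
        aucs = _fold_auc(col, y, groups, n_folds, seed)
        fold_rows[name] = aucs
        means[name] = float(np.nanmean(aucs)) if not all(np.isnan(aucs)) else np.nan
    mean_auc = pd.Series(means, name="mean_auc")
    rankable = mean_auc.dropna()
    ranking = list(rankable.sort_index().sort_values(ascending=False, kind="stable").index)
    rater = labels.rater if labels.scheme == "one_vote" else labels.name
    return ScreeningResult(
        rater=rater or labels.name,
        mean_auc=mean_auc,
        fold_auc=pd.DataFrame(fold_rows),
        ranking=ranking,
    )


def top_k_overlap(results: Sequence[ScreeningResult], k: int = 10) -> set:
    """Features present in every rater's top-k list."""
    if len(results) == 0:
        raise ValueError("need at least one screening result")
    overlap = set(results[0].top_k(k))
    for res in results[1:]:
        overlap &= set(res.top_k(k))
    return overlap


def fit_threshold_youden(scores, labels, feature: str = "", seed: Optional[int] = None) -> ThresholdModel:
    """Youden-index threshold plus a logistic fit on the raw feature.

    Candidate thresholds are the midpoints between consecutive sorted
    unique scores; the one maximising TPR - FPR wins, ties going to the
    smaller threshold.  The logistic slope/intercept are fitted on the
    unstandardised feature so ``implied_threshold`` reads directly on
    the feature scale.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("fit_threshold_youden needs both classes present")
    uniq = np.unique(x)
    if uniq.size < 2:
        raise ValueError("all scores identical; no threshold separates the classes")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        pred = x > t
        tpr = (pred & (y == 1)).sum() / n_pos
        fpr = (pred & (y == 0)).sum() / n_neg
        j = tpr - fpr
        if j > best_j:  # strict: ties keep the smaller threshold
            best_j, best_t = j, t
    sd = x.std() if x.std() > 0 else 1.0
    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=200)
    model.fit(((x - x.mean()) / sd).reshape(-1, 1), y)
    slope = float(model.coef_[0, 0] / sd)
    intercept = float(model.intercept_[0] - model.coef_[0, 0] * x.mean() / sd)
    in_range = bool(uniq[0] <= best_t <= uniq[-1])
    return ThresholdModel(
        feature=feature,
        slope=slope,
        intercept=intercept,
        threshold=float(best_t),
        youden_j=float(best_j),
        in_range=in_range,
        seed=seed,
    )


def _metrics_one(scores: pd.Series, predicted: pd.Series, truth: ConsensusSet) -> dict:
    ids = truth.labels.index.intersection(scores.index)
    if len(ids) == 0:
        raise ValueError(f"truth set {truth.name} covers none of the evaluated traces")
    y = truth.labels.loc[ids].to_numpy()
    s = scores.loc[ids].to_numpy(dtype=float)
    p = predicted.loc[ids].to_numpy(dtype=int)
    out = {
        "auc": float(roc_auc_score(y, s)) if len(np.unique(y)) > 1 else float("nan"),
        "average_precision": float(average_precision_score(y, s)),
        "f1": float(f1_score(y, p, zero_division=0)),
        "accuracy": float(accuracy_score(y, p)),
        "precision": float(precision_score(y, p, zero_division=0)),
        "recall": float(recall_score(y, p, zero_division=0)),
        "kappa": float(cohens_kappa(y, p)),
        "n": int(len(ids)),
    }
    return out


def evaluate(
    scores: pd.Series,
    predicted: pd.Series,
    truth: Union[ConsensusSet, Sequence[ConsensusSet]],
) -> dict:
    """The full metric set against one truth set or a list of 3-vote sets.

    Threshold-free metrics (AUC, average precision) come from the scores;
    thresholded metrics (F1, accuracy, precision, recall, Cohen's kappa)
    from the binary predictions.  Against a list of sets, each metric is
    reported as its mean and standard deviation across the sets.
    """
    if isinstance(truth, ConsensusSet):
        return _metrics_one(scores, predicted, truth)
    per_set = [_metrics_one(scores, predicted, t) for t in truth]
    keys = [k for k in per_set[0] if k != "n"]
    out: dict = {}
    for k in keys:
        vals = np.array([m[k] for m in per_set], dtype=float)
        out[k] = float(np.mean(vals))
        out[f"{k}_std"] = float(np.std(vals))
    out["n_sets"] = len(per_set)
    out["n"] = int(np.mean([m["n"] for m in per_set]))
    return out


def roc_pr_curves(scores, truth: Union[ConsensusSet, pd.Series]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full-sweep ROC and precision-recall curves as tidy tables.

    Returns ``(roc, pr)`` where ``roc`` has columns (threshold, fpr, tpr)
    and ``pr`` has (threshold, recall, precision).  The trapezoidal area
    under the returned ROC equals the scalar AUC reported by
    :func:`evaluate` on the same input.
    """
    labels = truth.labels if isinstance(truth, ConsensusSet) else truth
    if isinstance(scores, pd.Series) and isinstance(labels, pd.Series):
        ids = labels.index.intersection(scores.index)
        y = labels.loc[ids].to_numpy()
        s = scores.loc[ids].to_numpy(dtype=float)
    else:
        y = np.asarray(labels, dtype=int)
        s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_pr_curves needs both classes present")
    fpr, tpr, roc_thr = roc_curve(y, s)
    precision, recall, pr_thr = precision_recall_curve(y, s)
    roc_df = pd.DataFrame({"threshold": roc_thr, "fpr": fpr, "tpr": tpr})
    pr_df = pd.DataFrame(
        {
            "threshold": np.concatenate([pr_thr, [np.inf]]),
            "recall": recall,
            "precision": precision,
        }
    )
    return roc_df, pr_df


def curve_area(roc_df: pd.DataFrame) -> float:
    """Trapezoidal area under an emitted ROC curve table."""
    return float(curve_auc(roc_df["fpr"], roc_df["tpr"]))


def rater_operating_point(rater_labels: pd.Series, truth: ConsensusSet) -> dict:
    """A rater's single (FPR, TPR, recall, precision) point against a truth set.

    Raters assign binary labels, so on ROC / PR axes they appear as one
    point rather than a curve.
    """
    ids = truth.labels.index.intersection(rater_labels.index)
    y = truth.labels.loc[ids].to_numpy()
    p = rater_labels.loc[ids].to_numpy(dtype=int)
    tp = int(((p == 1) & (y == 1)).sum())
    fp = int(((p == 1) & (y == 0)).sum())
    fn = int(((p == 0) & (y == 1)).sum())
    tn = int(((p == 0) & (y == 0)).sum())
    return {
        "fpr": fp / (fp + tn) if fp + tn else float("nan"),
        "tpr": tp / (tp + fn) if tp + fn else float("nan"),
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "n": int(len(ids)),
    }
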