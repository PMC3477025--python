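"""Leave-one-out classifier evaluation and AUC machinery.

For a chosen feature set, a linear soft-margin SVM (C=1) is trained on all
subjects but one, with features standardized on the training fold, and the
signed decision value of the held-out subject is recorded; one ROC/AUC is
computed from the pooled scores of all folds.  Scores are never flipped:
pooled leave-one-out AUCs can legitimately fall below 0.5, and are reported
as-is.

AUC uses the Mann-Whitney form (tied pairs get half credit), which equals
the trapezoidal area under the pooled-score ROC.  AUC differences between
two evaluations on the same subjects are tested with DeLong's paired test
for correlated ROC curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .cohort import FeatureTable
from .stability import SelectionProfile, top_features

__all__ = [
    "EvaluationResult",
    "TopTCurve",
    "loo_scores",
    "auc",
    "compare_auc",
    "auc_vs_topT",
]


@dataclass
class EvaluationResult:
    """Pooled leave-one-out decision scores and the resulting AUC."""

    feature_set: list[str]
    subject_ids: list[str]
    loo_scores: np.ndarray
    labels: np.ndarray
    auc: float
    roc_points: np.ndarray            # (FPR, TPR) rows
    classifier_config: dict = field(default_factory=dict)
    n_dropped: int = 0                # subjects dropped for missing values

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "subject_ids": self.subject_ids,
            "scores": [float(s) for s in self.loo_scores],
            "labels": [int(v) for v in self.labels],
            "auc": float(self.auc),
            "roc_points": [[float(a), float(b)] for a, b in self.roc_points],
            "classifier": self.classifier_config,
            "n_dropped": self.n_dropped,
        }


@dataclass
class TopTCurve:
    """AUC as a function of the number of top-ranked features used."""

    t_values: np.ndarray
    aucs: np.ndarray
    ranking: list[str]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"T": self.t_values, "auc": self.aucs})


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: (concordant pairs + half the ties) / (n_pos*n_neg).

    Computed from average ranks, so tied scores receive exactly half credit;
    equals the trapezoidal area under the threshold ROC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def loo_scores(table: FeatureTable, feature_set: Sequence[str],
               C: float = 1.0) -> EvaluationResult:
    """Leave-one-out evaluation of a feature set with a linear SVM.

    Subjects with missing values on the chosen features are dropped (count
    recorded on the result).  Per fold, features are standardized on the
    n-1 training subjects only; the held-out subject's signed distance to
    the margin is its pooled score.  Fully deterministic.
    """
    feature_set = list(feature_set)
    if not feature_set:
        raise ValueError("feature set must be non-empty")
    sub = table.subset_features(feature_set)
    keep = ~np.isnan(sub.X).any(axis=1)
    n_dropped = int((~keep).sum())
    X = sub.X[keep]
    y = sub.labels[keep]
    ids = [s for s, k in zip(sub.subject_ids, keep) if k]
    n = len(y)
    if (y == 1).sum() < 2 or (y == -1).sum() < 2:
        raise ValueError("need at least two subjects per class")

    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd < 1e-12] = 1.0
        clf = SVC(kernel="linear", C=C)
        clf.fit((Xtr - mu) / sd, ytr)
        scores[i] = clf.decision_function(((X[i] - mu) / sd)[None, :])[0]

    a = auc(scores, y)
    fpr, tpr, _ = roc_curve(y, scores)
    return EvaluationResult(
        feature_set=feature_set,
        subject_ids=ids,
        loo_scores=scores,
        labels=y,
        auc=a,
        roc_points=np.column_stack([fpr, tpr]),
        classifier_config={"kernel": "linear", "C": C, "standardize": "per-fold"},
        n_dropped=n_dropped,
    )


def _delong_variance(scores: np.ndarray, labels: np.ndarray
                     ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement components V10 (per positive), V01 (per
    negative) for one score vector."""
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa, ties half
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    return float(v10.mean()), v10, v01


def compare_auc(result_a: EvaluationResult, result_b: EvaluationResult
                ) -> float:
    """DeLong's paired two-sided test for equality of two correlated AUCs.

    Both evaluations must cover the identical subject set (same order); the
    pooled leave-one-out scores are compared directly.  Returns the two-sided
    p-value; identical score vectors give p = 1.
    """
    if result_a.subject_ids != result_b.subject_ids:
        raise ValueError("evaluations must cover the identical subject set")
    labels = result_a.labels
    sa, sb = result_a.loo_scores, result_b.loo_scores
    auc_a, v10_a, v01_a = _delong_variance(sa, labels)
    auc_b, v10_b, v01_b = _delong_variance(sb, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]))      # 2x2 over positives
    s01 = np.cov(np.vstack([v01_a, v01_b]))      # 2x2 over negatives
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def paired_bootstrap_auc_test(result_a: EvaluationResult,
                              result_b: EvaluationResult,
                              n_resamples: int = 2000,
                              seed: int = 0) -> float:
    """Paired-bootstrap test of AUC equality (independent cross-check for
    :func:`compare_auc`): resample subjects with replacement, recompute the
    AUC difference, and invert the percentile interval into a two-sided p."""
    if result_a.subject_ids != result_b.subject_ids:
        raise ValueError("evaluations must cover the identical subject set")
    labels = result_a.labels
    sa, sb = result_a.loo_scores, result_b.loo_scores
    rng = np.random.default_rng(seed)
    n = len(labels)
    diffs = np.empty(n_resamples)
    k = 0
    while k < n_resamples:
        idx = rng.integers(0, n, size=n)
        lab = labels[idx]
        if (lab == 1).sum() == 0 or (lab == -1).sum() == 0:
            continue
        diffs[k] = auc(sa[idx], lab) - auc(sb[idx], lab)
        k += 1
    observed = result_a.auc - result_b.auc
    if np.allclose(sa, sb):
        return 1.0
    # two-sided: twice the smaller tail of the centered bootstrap distribution
    centered = diffs - diffs.mean()
    p = 2.0 * min((centered >= abs(observed)).mean(),
                  (centered <= -abs(observed)).mean())
    return float(min(max(p, 1.0 / n_resamples), 1.0))


def auc_vs_topT(table: FeatureTable, profile: SelectionProfile,
                t_max: int = 30, C: float = 1.0) -> TopTCurve:
    """Leave-one-out AUC using the top T stability-ranked features,
    for T = 1..t_max."""
    t_max = min(t_max, len(profile.feature_names))
    ranking = top_features(profile, t_max)
    aucs = np.empty(t_max)
    for t in range(1, t_max + 1):
        aucs[t - 1] = loo_scores(table, ranking[:t], C=C).auc
    return TopTCurve(t_values=np.arange(1, t_max + 1), aucs=aucs,
                     ranking=ranking)
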