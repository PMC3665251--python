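"""Cross-validated decoding of condition labels from trial-beta patterns.

A linear maximum-margin classifier (soft-margin linear SVM, C = 1) is
evaluated with stratified 5-fold cross-validation on the trials x voxels
beta matrix; features are standardized on the training folds only.
Method comparisons across subjects or seeds use the two-sided Wilcoxon
signed-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .trial_betas import TrialBetaMatrix

__all__ = ["DecodingResult", "cross_validated_accuracy", "wilcoxon_paired"]


@dataclass
class DecodingResult:
    fold_accuracies: np.ndarray
    mean_accuracy: float
    method_tag: str
    n_folds: int
    seed: int

    def __post_init__(self):
        acc = np.asarray(self.fold_accuracies, dtype=float)
        if np.any((acc < 0) | (acc > 1)):
            raise ValueError("fold accuracies must lie in [0, 1]")
        if not np.isclose(self.mean_accuracy, acc.mean()):
            raise ValueError("mean_accuracy must equal the mean of the folds")


def cross_validated_accuracy(
    features,
    n_folds: int = 5,
    seed: int = 0,
    method_tag: str = "",
    C: float = 1.0,
) -> DecodingResult:
    """Stratified k-fold accuracy of a linear SVM on trial betas.

    ``features`` is a :class:`TrialBetaMatrix` or an ``(X, labels)`` pair.
    Trials with non-finite betas are dropped beforehand. Each class must
    have at least ``n_folds`` trials so every training fold sees every
    class.
    """
    if isinstance(features, TrialBetaMatrix):
        features = features.drop_nonfinite()
        X, labels = features.betas, features.labels
    else:
        X, labels = features
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to decode")
    if counts.min() < n_folds:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has {counts.min()} trials, "
            f"fewer than n_folds={n_folds}; cannot stratify"
        )
    clf = make_pipeline(StandardScaler(), LinearSVC(C=C))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(X, labels):
        clf.fit(X[train_idx], labels[train_idx])
        accs.append(float(np.mean(clf.predict(X[test_idx]) == labels[test_idx])))
    accs = np.asarray(accs)
    return DecodingResult(
        fold_accuracies=accs,
        mean_accuracy=float(accs.mean()),
        method_tag=method_tag,
        n_folds=n_folds,
        seed=seed,
    )


def wilcoxon_paired(acc_a, acc_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired accuracies.

    Zero differences are discarded (the classic zero-discard convention);
    if every difference is zero the test is undefined and p = 1 is
    returned with a warning. The exact null distribution is used when the
    sample is small enough and untied.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("acc_a and acc_b must be equal-length vectors")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p-value set to 1",
                      stacklevel=2)
        return 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                         method="auto")
    return float(res.pvalue)


def sign_test_pvalue(diffs) -> float:
    """One-sided sign-test p-value that the median difference is > 0.

    Zero differences are discarded; the p-value is the binomial tail
    probability of at least the observed number of positive signs under
    p = 1/2.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    k = int(np.sum(d > 0))
    return float(stats.binomtest(k, len(d), 0.5, alternative="greater").pvalue)
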