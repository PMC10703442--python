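"""Linear-discriminant decoding of sequence identity and strategy context.

Classifiers are trained on windowed firing rates (counts / window width by
default) of all active units, with class balancing and a single stratified
five-fold cross-validation; the reported value is the mean held-out error
rate across the five folds.  The discriminant uses a pooled covariance
shrunk toward its diagonal, since the feature count (units x windows) can
approach the instance count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ClassifierSpec",
    "ClassifierResult",
    "balance_classes",
    "fit_sequence_classifier",
    "decode_action_context",
]

RATE = "RATE"
SQRT_COUNT = "SQRT_COUNT"
SIDE_PORT = "SIDE_PORT"
CENTER_PORT = "CENTER_PORT"


@dataclass(frozen=True)
class ClassifierSpec:
    anchor_mode: str = SIDE_PORT
    windows_used: tuple = (1, 2, 3)  # sequence steps contributing windows
    folds: int = 5
    balance: bool = True
    feature_transform: str = RATE
    shrinkage: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not self.windows_used:
            raise ValueError("windows_used must be non-empty")


@dataclass
class ClassifierResult:
    mean_cv_error: float
    per_fold_errors: np.ndarray
    n_per_class: int
    labels: tuple


def balance_classes(features: np.ndarray, labels, seed: int = 0):
    """Random subsample of the majority class(es) down to the minority count.

    Returns ``(features, labels, kept_index)``; reproducible under ``seed``.
    """
    labels = np.asarray(labels)
    names, counts = np.unique(labels, return_counts=True)
    if len(names) < 2:
        raise ValueError("need at least 2 classes")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep = []
    for name in names:
        idx = np.flatnonzero(labels == name)
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(np.sort(idx))
    keep = np.sort(np.concatenate(keep))
    return features[keep], labels[keep], keep


class _ShrunkLDA:
    """Two-class linear discriminant with diagonal-shrunk pooled covariance."""

    def __init__(self, shrinkage: float = 0.1):
        self.shrinkage = shrinkage

    def fit(self, X: np.ndarray, y: np.ndarray):
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary labels required")
        mus, resid = [], []
        for c in self.classes_:
            Xc = X[y == c]
            mus.append(Xc.mean(axis=0))
            resid.append(Xc - Xc.mean(axis=0))
        resid = np.vstack(resid)
        n = len(X)
        cov = resid.T @ resid / max(n - 2, 1)
        cov = (1 - self.shrinkage) * cov + self.shrinkage * np.diag(np.diag(cov))
        # small absolute floor keeps all-silent features from making the
        # pooled covariance exactly singular
        cov += 1e-9 * np.trace(cov) / max(len(cov), 1) * np.eye(len(cov))
        try:
            w = linalg.solve(cov, mus[1] - mus[0], assume_a="pos")
        except linalg.LinAlgError as exc:  # pragma: no cover - diagnostic path
            raise np.linalg.LinAlgError(
                f"singular pooled covariance after shrinkage "
                f"{self.shrinkage}: {exc}"
            )
        self.w_ = w
        self.b_ = -0.5 * float(w @ (mus[0] + mus[1]))
        return self

    def predict(self, X: np.ndarray):
        score = X @ self.w_ + self.b_
        return np.where(score > 0, self.classes_[1], self.classes_[0])


def fit_sequence_classifier(
    features: np.ndarray, labels, spec: ClassifierSpec | None = None
) -> ClassifierResult:
    """Cross-validated LDA error for a binary comparison.

    ``features`` is instances x features (rates of all active units in the
    selected windows).  Classes are balanced first (when ``spec.balance``),
    then a single stratified ``spec.folds``-fold split is drawn and five
    classifiers are trained, each scored on its held-out 20%.
    """
    spec = spec or ClassifierSpec()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if spec.balance:
        features, labels, _ = balance_classes(features, labels, seed=spec.seed)
    names, counts = np.unique(labels, return_counts=True)
    if len(names) != 2:
        raise ValueError("binary labels required")
    if counts.min() < spec.folds:
        raise ValueError(
            f"each class needs >= {spec.folds} members, got {counts.min()}"
        )
    skf = StratifiedKFold(
        n_splits=spec.folds, shuffle=True, random_state=spec.seed
    )
    errors = []
    for train, test in skf.split(features, labels):
        clf = _ShrunkLDA(shrinkage=spec.shrinkage).fit(
            features[train], labels[train]
        )
        errors.append(float(np.mean(clf.predict(features[test]) != labels[test])))
    errors = np.asarray(errors)
    return ClassifierResult(
        mean_cv_error=float(errors.mean()),
        per_fold_errors=errors,
        n_per_class=int(counts.min()),
        labels=tuple(names),
    )


def decode_action_context(
    tensor,
    window: int,
    contexts,
    spec: ClassifierSpec | None = None,
) -> ClassifierResult:
    """Decode the sequence context of a fixed action from a single window.

    ``tensor`` is an :class:`~seqprev.statespace.InstanceActivityTensor`
    restricted to instances of a matched action; ``window`` selects the one
    decoding window; ``contexts`` gives the binary label per instance (e.g.
    which sequence the action was embedded in).
    """
    spec = spec or ClassifierSpec()
    if spec.feature_transform == RATE:
        feats = tensor.counts()[:, :, window] / tensor.spec.width
    else:
        feats = tensor.values[:, :, window]
    return fit_sequence_classifier(feats, contexts, spec)
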