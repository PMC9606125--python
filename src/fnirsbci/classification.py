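"""Linear-SVM detection of impulse vs. non-impulse buying.

The classifier is a linear support-vector machine trained with the
SMO dual solver (libsvm via scikit-learn's ``SVC``) at fixed C = 1.0.
The classification unit is the per-time-sample five-feature vector;
for each subject the two sessions' rows are pooled (496 + 496 rows,
binary label = session) and evaluated with stratified tenfold
cross-validation.  Feature rescaling is fit on the training folds
only by default (``pooled_scaling=True`` fits on all rows instead).

Accuracy is reported per fold and per subject; the cohort summary is
the grand mean of subject accuracies with its standard error
(sd across subjects / sqrt(n_subjects)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .features import FEATURE_NAMES, FeatureMatrix

__all__ = ["CVResult", "train_svm", "crossvalidate"]


def train_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> SVC:
    """Fit a linear-kernel SVM (SMO dual solver) on one training set."""
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(
            f"training set contains a single class ({classes.tolist()}); "
            f"need both conditions")
    # tight SMO convergence tolerance for reproducible decision functions
    model = SVC(kernel="linear", C=C, tol=1e-5)
    model.fit(X, y)
    return model


@dataclass
class CVResult:
    """Per-subject and cohort cross-validation accuracies."""

    folds: pd.DataFrame            # columns: subject, fold, n_test, accuracy
    seed: int
    k: int
    fold_assignment: dict[str, list[int]] = field(default_factory=dict)

    @property
    def subject_means(self) -> pd.Series:
        return self.folds.groupby("subject")["accuracy"].mean()

    @property
    def grand_mean(self) -> float:
        return float(self.subject_means.mean())

    @property
    def sem(self) -> float:
        m = self.subject_means
        if len(m) < 2:
            return float("nan")
        return float(m.std(ddof=1) / np.sqrt(len(m)))

    def summary(self) -> dict:
        return {
            "grand_mean_accuracy": self.grand_mean,
            "sem": self.sem,
            "n_subjects": int(self.folds["subject"].nunique()),
            "k": self.k,
            "seed": self.seed,
            "subject_accuracy_min": float(self.subject_means.min()),
            "subject_accuracy_max": float(self.subject_means.max()),
        }


def _scale_train_test(Xtr: np.ndarray, Xte: np.ndarray,
                      pooled_scaling: bool) -> tuple[np.ndarray, np.ndarray]:
    ref = np.vstack([Xtr, Xte]) if pooled_scaling else Xtr
    lo, hi = ref.min(axis=0), ref.max(axis=0)
    span = hi - lo
    if np.any(span <= 0):
        bad = FEATURE_NAMES[int(np.argmax(span <= 0))]
        raise ValueError(f"feature {bad!r} constant on the scaling partition")
    return (Xtr - lo) / span, (Xte - lo) / span


def crossvalidate(fm: FeatureMatrix, k: int = 10, seed: int = 0,
                  C: float = 1.0, stratified: bool = True,
                  pooled_scaling: bool = False,
                  repeats: int = 1) -> CVResult:
    """Within-subject stratified k-fold CV of the linear SVM.

    Each subject's pooled rows are shuffled (seeded per subject),
    split into ``k`` folds, rescaled on the training rows, classified,
    and scored on the held-out fold.  ``repeats`` > 1 re-runs the CV
    with fresh shuffles and averages into the same table (a repeat-CV
    reading of the protocol; off by default).
    """
    table = fm.table
    records = []
    assignment: dict[str, list[int]] = {}
    subjects = sorted(table["subject"].unique())
    for si, subject in enumerate(subjects):
        sub = table[table["subject"] == subject]
        X = sub[list(FEATURE_NAMES)].to_numpy()
        y = sub["session"].to_numpy()
        if np.unique(y).size < 2:
            raise ValueError(f"subject {subject}: rows from a single session only")
        if len(sub) < k:
            raise ValueError(f"subject {subject}: fewer rows ({len(sub)}) than folds ({k})")
        for rep in range(repeats):
            rs = int(np.random.SeedSequence([seed, si, rep]).generate_state(1)[0]
                     % (2 ** 31))
            splitter = (StratifiedKFold if stratified else KFold)(
                n_splits=k, shuffle=True, random_state=rs)
            fold_of_row = np.full(len(sub), -1, dtype=int)
            for fold, (tr, te) in enumerate(splitter.split(X, y)):
                fold_of_row[te] = fold
                Xtr, Xte = _scale_train_test(X[tr], X[te], pooled_scaling)
                model = train_svm(Xtr, y[tr], C=C)
                acc = float(np.mean(model.predict(Xte) == y[te]))
                records.append({"subject": subject, "repeat": rep, "fold": fold,
                                "n_test": len(te), "accuracy": acc})
            if np.any(fold_of_row < 0) or np.bincount(fold_of_row).sum() != len(sub):
                raise AssertionError("fold assignment is not a partition")
            if rep == 0:
                assignment[subject] = fold_of_row.tolist()
    folds = pd.DataFrame(records)
    return CVResult(folds=folds, seed=seed, k=k, fold_assignment=assignment)
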