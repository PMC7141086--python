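"""SVM classification of candidate peaks and leave-one-subject-out evaluation.

An RBF-kernel support vector machine separates hazard-evoked dilation peaks
from spurious ones using the 7 wavelet features.  Hazard peaks are rare
(nine per 40-minute drive against dozens of spontaneous fluctuation peaks),
so each training fold balances the classes by oversampling the minority
class before fitting.  Generalization is measured leave-one-subject-out:
each subject's candidates are scored by a model trained exclusively on the
other subjects.

Sensitivity is reported at the *event* level — a hazard that produced no
candidate at all counts as a false negative — while specificity and
precision operate on the candidate level, where true negatives exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import EvaluationReport, compute_rates
from .features import FEATURE_NAMES, LABEL_HAZARD

logger = logging.getLogger(__name__)


@dataclass
class ClassifierConfig:
    C: float = 1.0
    gamma: str | float = "scale"  # 1 / (n_features * feature variance)
    oversample_seed: int = 0
    standardize: bool = True
    decision_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not isinstance(self.gamma, str) and self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class FoldResult:
    """Held-out predictions for one subject's candidates.

    ``fn`` includes the subject's hazard events that never produced a
    candidate (``n_missed_events``), so sensitivity is event-level.
    """

    held_out_subject: str
    scores: np.ndarray
    predicted: np.ndarray  # bool, hazard prediction at the fold threshold
    truth: np.ndarray  # bool, hazard label
    n_missed_events: int = 0

    @property
    def tp(self) -> int:
        return int(np.sum(self.predicted & self.truth))

    @property
    def fp(self) -> int:
        return int(np.sum(self.predicted & ~self.truth))

    @property
    def tn(self) -> int:
        return int(np.sum(~self.predicted & ~self.truth))

    @property
    def fn(self) -> int:
        return int(np.sum(~self.predicted & self.truth)) + self.n_missed_events


def oversample_minority(
    X: np.ndarray, y: np.ndarray, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Balance classes by duplicating minority rows uniformly at random with
    replacement until the counts are equal.  Majority rows are untouched and
    the set of distinct minority points never changes."""
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        present = classes[0] if len(classes) else "none"
        raise ValueError(f"both classes required for oversampling; only {present!r} present")
    minority = classes[np.argmin(counts)]
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    pool = np.flatnonzero(y == minority)
    extra = rng.choice(pool, size=deficit, replace=True)
    return np.vstack([X, X[extra]]), np.concatenate([y, y[extra]])


def train(X: np.ndarray, y: np.ndarray, config: Optional[ClassifierConfig] = None) -> Pipeline:
    """Fit the RBF SVM on a (balanced) training set.

    Features are z-scored with training statistics when
    ``config.standardize``; a zero-variance feature standardizes to 0 (a
    warning is logged) rather than poisoning the kernel.
    """
    if config is None:
        config = ClassifierConfig()
    X = np.asarray(X, dtype=float)
    steps = []
    if config.standardize:
        if np.any(np.var(X, axis=0) == 0):
            logger.warning("zero-variance feature(s); standardized values set to 0")
        steps.append(("scale", StandardScaler()))
    steps.append(("svc", SVC(kernel="rbf", C=config.C, gamma=config.gamma)))
    model = Pipeline(steps)
    model.fit(X, y)
    return model


def decision_scores(model: Pipeline, X: np.ndarray) -> np.ndarray:
    """Real-valued decision score per input; positive means hazard."""
    scores = model.decision_function(np.asarray(X, dtype=float))
    # sklearn orients decision_function toward the lexically larger class;
    # flip if needed so that larger score always means hazard
    svc = model.named_steps["svc"]
    if list(svc.classes_)[-1] != LABEL_HAZARD and LABEL_HAZARD in list(svc.classes_):
        scores = -scores
    return scores


def loso_cv(
    dataset: pd.DataFrame,
    config: Optional[ClassifierConfig] = None,
    missed_events: Optional[Dict[str, int]] = None,
) -> List[FoldResult]:
    """Leave-one-subject-out cross-validation over a labelled feature table.

    ``dataset`` needs columns ``subject``, the 7 feature columns and
    ``label``.  Oversampling is applied inside each training fold only —
    never to the held-out subject.  A fold whose training set lacks a class
    is skipped with a warning.
    """
    if config is None:
        config = ClassifierConfig()
    missed_events = missed_events or {}
    # canonical row order makes folds (and the oversampling draw) invariant
    # to how the caller ordered subjects or candidates
    dataset = dataset.sort_values(["subject", "peak_time"], kind="stable")
    subjects = list(dict.fromkeys(dataset["subject"]))
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    results: List[FoldResult] = []
    X_all = dataset[FEATURE_NAMES].to_numpy(dtype=float)
    y_all = dataset["label"].to_numpy()
    subj_all = dataset["subject"].to_numpy()
    for subject in sorted(subjects):
        test = subj_all == subject
        X_train, y_train = X_all[~test], y_all[~test]
        if len(np.unique(y_train)) < 2:
            logger.warning("fold %s skipped: training set missing a class", subject)
            continue
        Xb, yb = oversample_minority(X_train, y_train, seed=config.oversample_seed)
        model = train(Xb, yb, config)
        scores = decision_scores(model, X_all[test])
        results.append(
            FoldResult(
                held_out_subject=subject,
                scores=scores,
                predicted=scores > config.decision_threshold,
                truth=y_all[test] == LABEL_HAZARD,
                n_missed_events=int(missed_events.get(subject, 0)),
            )
        )
    return results


def roc_points(scores: np.ndarray, truth: np.ndarray) -> List[Tuple[float, float, float]]:
    """ROC from sweeping the decision threshold over all observed scores.

    Returns (false_positive_rate, true_positive_rate, threshold) triples,
    threshold descending, starting at (0, 0, +inf).  Tied scores collapse
    onto one point.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    P = int(truth.sum())
    N = int((~truth).sum())
    points = [(0.0, 0.0, float("inf"))]
    if P == 0 or N == 0:
        return points
    order = np.argsort(-scores, kind="stable")
    tp = fp = 0
    sorted_scores = scores[order]
    sorted_truth = truth[order]
    i = 0
    while i < len(sorted_scores):
        thr = sorted_scores[i]
        while i < len(sorted_scores) and sorted_scores[i] == thr:
            if sorted_truth[i]:
                tp += 1
            else:
                fp += 1
            i += 1
        points.append((fp / N, tp / P, float(thr)))
    return points


def trapezoid_auc(points: List[Tuple[float, float, float]]) -> Optional[float]:
    """Area under the ROC by the trapezoid rule; None for a degenerate ROC."""
    if len(points) < 2:
        return None
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    return float(np.trapezoid(tpr, fpr))


def evaluate(fold_results: List[FoldResult]) -> EvaluationReport:
    """Aggregate held-out folds into a per-subject and pooled report.

    Zero-denominator rates are left undefined (None) and flagged in
    ``report.warnings``.  ``candidate_counts`` records, per subject, the
    number of candidate peaks D entering classification and the number of
    false positives F surviving it.
    """
    report = EvaluationReport()
    tp = fp = tn = fn = 0
    all_scores, all_truth = [], []
    for fold in fold_results:
        m = compute_rates(fold.tp, fold.fp, fold.tn, fold.fn)
        report.per_subject[fold.held_out_subject] = m
        report.candidate_counts[fold.held_out_subject] = (len(fold.scores), fold.fp)
        for rate in ("sensitivity", "specificity", "precision"):
            if getattr(m, rate) is None:
                report.warnings.append(f"{fold.held_out_subject}: {rate} undefined")
        tp += fold.tp
        fp += fold.fp
        tn += fold.tn
        fn += fold.fn
        all_scores.append(fold.scores)
        all_truth.append(fold.truth)
    report.pooled = compute_rates(tp, fp, tn, fn)
    if all_scores:
        scores = np.concatenate(all_scores)
        truth = np.concatenate(all_truth)
        report.roc = roc_points(scores, truth)
        report.auc = trapezoid_auc(report.roc)
    return report
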