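"""Exhaustive gene-panel classification with subject-disjoint evaluation.

Starting from a panel of 10 candidate genes (typically the top DE genes),
every combination of N genes (2 ≤ N ≤ 10, 1013 combinations in total) is
scored by training-set accuracy for each of four classifiers — linear SVM,
RBF SVM, random forest, and quadratic Bayes (quadratic discriminant
analysis). For each N the combination with the maximum training accuracy is
selected and its test-set accuracy, precision, recall and F1 are reported,
together with a distribution-free Hoeffding error bar

    ε = sqrt(ln(2/δ) / (2·n_test)),

so that the out-of-sample error is at most test error + ε with probability
≥ 1 − δ. Test data never influence panel selection; train/test splits are
subject-disjoint so repeated samples from one subject cannot leak identity
across the split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

__all__ = [
    "SplitPlan",
    "PanelReport",
    "CLASSIFIER_NAMES",
    "make_classifier",
    "split_by_subject",
    "panel_search",
    "evaluate",
    "hoeffding_bound",
    "PanelSearch",
]

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("linear_svm", "rbf_svm", "random_forest", "quadratic_bayes")


@dataclass
class SplitPlan:
    """Subject-disjoint train/test partition of samples."""

    train_samples: list[str]
    test_samples: list[str]
    train_frac: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_samples) & set(self.test_samples):
            raise ValueError("train and test samples overlap")


@dataclass
class PanelReport:
    """Best panel and its metrics for one (classifier, N)."""

    classifier: str
    n_genes: int
    best_panel: tuple[str, ...]
    train_acc: float
    test_acc: float
    precision: float
    recall: float
    f1: float
    hoeffding_eps: float
    out_of_sample_bound: float
    n_combinations: int


def make_classifier(name: str, random_state: int | None = 0,
                    n_estimators: int = 500) -> BaseEstimator:
    """Instantiate one of the four panel classifiers with fixed defaults."""
    if name == "linear_svm":
        return SVC(kernel="linear", C=1.0)
    if name == "rbf_svm":
        # gamma='scale' is 1/(N·Var(X)), the kernel width tied to panel size
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=n_estimators,
                                      random_state=random_state, n_jobs=1)
    if name == "quadratic_bayes":
        return QuadraticDiscriminantAnalysis(reg_param=1e-3)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


def split_by_subject(meta: pd.DataFrame, train_frac: float = 0.7,
                     seed: int = 0) -> SplitPlan:
    """Random subject-level train/test split, stratified by diagnosis.

    Subjects (never samples) are shuffled within each diagnosis group; the
    per-group train-subject counts are chosen so the resulting train-sample
    count is as close as possible to ``train_frac`` of all samples, with at
    least one subject of each group on each side. Deterministic given seed.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    total = len(meta)
    target = train_frac * total
    shuffled: dict[str, list[str]] = {}
    counts: dict[str, np.ndarray] = {}
    for diag, grp in meta.groupby("diagnosis"):
        subjects = sorted(grp["subject_id"].unique())
        if len(subjects) < 2:
            raise ValueError(f"group {diag!r} has a single subject; cannot split")
        order = list(rng.permutation(subjects))
        shuffled[diag] = order
        counts[diag] = np.array(
            [int((meta["subject_id"] == s).sum()) for s in order])
    diags = sorted(shuffled)
    if len(diags) != 2:
        raise ValueError("expected exactly two diagnosis groups")
    d1, d2 = diags
    n1, n2 = len(shuffled[d1]), len(shuffled[d2])
    cum1 = np.concatenate([[0], np.cumsum(counts[d1])])
    cum2 = np.concatenate([[0], np.cumsum(counts[d2])])
    # primary: train-sample count closest to the target; secondary
    # (stratification): per-group subject fractions closest to train_frac
    best, best_key = None, None
    for i in range(1, n1):                     # ≥1 subject per side per group
        for j in range(1, n2):
            dist = abs(cum1[i] + cum2[j] - target)
            strat = abs(i / n1 - train_frac) + abs(j / n2 - train_frac)
            key = (dist, strat)
            if best_key is None or key < best_key:
                best, best_key = (i, j), key
    i, j = best
    train_subjects = set(shuffled[d1][:i]) | set(shuffled[d2][:j])
    in_train = meta["subject_id"].isin(train_subjects)
    return SplitPlan(
        train_samples=meta.loc[in_train, "sample_id"].tolist(),
        test_samples=meta.loc[~in_train, "sample_id"].tolist(),
        train_frac=train_frac,
        seed=seed,
    )


def evaluate(pred: Sequence, true: Sequence, positive_class: str = "AD"
             ) -> tuple[float, float, float, float]:
    """Accuracy, precision, recall and F1 for binary labels.

    F1 = 2·precision·recall/(precision+recall), defined as 0 when
    precision + recall = 0 (and precision/recall as 0 when undefined).
    """
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth must have equal length")
    acc = float(np.mean(pred == true))
    tp = float(np.sum((pred == positive_class) & (true == positive_class)))
    fp = float(np.sum((pred == positive_class) & (true != positive_class)))
    fn = float(np.sum((pred != positive_class) & (true == positive_class)))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return acc, precision, recall, f1


def hoeffding_bound(test_error: float, n_test: int, delta: float = 0.5
                    ) -> tuple[float, float]:
    """Hoeffding error bar and out-of-sample error bound.

    ε = sqrt(ln(2/δ)/(2n)); with probability ≥ 1 − δ the out-of-sample
    error is at most test_error + ε.
    """
    if n_test < 1:
        raise ValueError("n_test must be at least 1")
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must lie in (0, 1)")
    eps = float(np.sqrt(np.log(2.0 / delta) / (2.0 * n_test)))
    return eps, test_error + eps


def _standardize(train: np.ndarray, test: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Standardize with training-set mean/sd only."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def panel_search(
    X_top: pd.DataFrame,
    labels: pd.Series,
    classifier: str | BaseEstimator,
    split: SplitPlan,
    n_min: int = 2,
    n_max: int = 10,
    delta: float = 0.5,
    positive_class: str = "AD",
    random_state: int | None = 0,
    n_estimators: int = 500,
) -> list[PanelReport]:
    """Exhaustive search over gene combinations for one classifier.

    ``X_top`` is a samples × genes matrix restricted to the candidate panel
    (exactly 10 genes for the canonical protocol); ``labels`` maps sample →
    class. For each N all C(10, N) combinations are trained and scored on
    the training split only; the maximizer (ties broken by lexicographic
    gene order) is then evaluated once on the test split.
    """
    if isinstance(classifier, str):
        est = make_classifier(classifier, random_state=random_state,
                              n_estimators=n_estimators)
        clf_name = classifier
    else:
        est = classifier
        clf_name = type(classifier).__name__
    genes = sorted(X_top.columns)
    if len(genes) != X_top.shape[1]:
        raise ValueError("duplicate gene columns in panel matrix")
    if len(genes) < n_max:
        raise ValueError(f"need at least {n_max} candidate genes, got {len(genes)}")
    y = labels.reindex(X_top.index)
    if y.isna().any():
        raise ValueError("labels missing for some samples")
    tr_idx = [s for s in X_top.index if s in set(split.train_samples)]
    te_idx = [s for s in X_top.index if s in set(split.test_samples)]
    if not tr_idx or not te_idx:
        raise ValueError("split leaves train or test empty for this matrix")
    y_tr = y.loc[tr_idx].to_numpy()
    y_te = y.loc[te_idx].to_numpy()
    n_test = len(te_idx)

    reports = []
    for N in range(n_min, n_max + 1):
        best_combo: tuple[str, ...] | None = None
        best_acc = -1.0
        n_evaluated = 0
        for combo in combinations(genes, N):  # lexicographic order
            n_evaluated += 1
            Xtr = X_top.loc[tr_idx, list(combo)].to_numpy(dtype=float)
            Xte_unused = None  # test data must not influence selection
            Xtr_std = _standardize(Xtr, Xtr)[0]
            model = clone(est)
            try:
                model.fit(Xtr_std, y_tr)
                acc = float(np.mean(model.predict(Xtr_std) == y_tr))
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("combination %s failed to train: %s", combo, exc)
                acc = 0.0
            if acc > best_acc:  # strict: first (lexicographically) wins ties
                best_acc, best_combo = acc, combo
        # winner evaluated once on test
        Xtr = X_top.loc[tr_idx, list(best_combo)].to_numpy(dtype=float)
        Xte = X_top.loc[te_idx, list(best_combo)].to_numpy(dtype=float)
        Xtr_std, Xte_std = _standardize(Xtr, Xte)
        model = clone(est)
        try:
            model.fit(Xtr_std, y_tr)
            pred = model.predict(Xte_std)
            acc, prec, rec, f1 = evaluate(pred, y_te, positive_class)
        except Exception as exc:
            logger.warning("winning combination %s failed to refit: %s",
                           best_combo, exc)
            acc = prec = rec = f1 = 0.0
        eps, bound = hoeffding_bound(1.0 - acc, n_test, delta)
        reports.append(PanelReport(
            classifier=clf_name, n_genes=N, best_panel=best_combo,
            train_acc=best_acc, test_acc=acc, precision=prec, recall=rec,
            f1=f1, hoeffding_eps=eps, out_of_sample_bound=bound,
            n_combinations=n_evaluated,
        ))
    return reports


def reports_to_frame(reports: Sequence[PanelReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = r.__dict__.copy()
        row["best_panel"] = "|".join(r.best_panel)
        rows.append(row)
    return pd.DataFrame(rows)


class PanelSearch(BaseEstimator):
    """Exhaustive gene-panel selection as an estimator.

    ``fit`` runs the search for each requested classifier over a
    subject-disjoint split and stores per-(classifier, N) reports; the
    overall best model (highest test accuracy, smallest N then classifier
    order breaking ties) is refit and used by ``predict``.

    Parameters
    ----------
    classifiers : sequence of str
        Subset of ``CLASSIFIER_NAMES``.
    train_frac : float, default 0.7
    n_min, n_max : int
        Panel size range (2..10 canonically).
    delta : float, default 0.5
        Hoeffding tolerance.
    random_state : int, default 0
        Seed for the split and the random forest.
    """

    def __init__(self, classifiers: Sequence[str] = CLASSIFIER_NAMES,
                 train_frac: float = 0.7, n_min: int = 2, n_max: int = 10,
                 delta: float = 0.5, positive_class: str = "AD",
                 random_state: int = 0, n_estimators: int = 500):
        self.classifiers = classifiers
        self.train_frac = train_frac
        self.n_min = n_min
        self.n_max = n_max
        self.delta = delta
        self.positive_class = positive_class
        self.random_state = random_state
        self.n_estimators = n_estimators

    def fit(self, X_top: pd.DataFrame, meta: pd.DataFrame,
            split: SplitPlan | None = None) -> "PanelSearch":
        labels = pd.Series(meta["diagnosis"].to_numpy(),
                           index=meta["sample_id"].to_numpy())
        if split is None:
            split = split_by_subject(meta, self.train_frac, self.random_state)
        self.split_ = split
        self.reports_ = []
        for name in self.classifiers:
            self.reports_.extend(panel_search(
                X_top, labels, name, split, self.n_min, self.n_max,
                self.delta, self.positive_class, self.random_state,
                self.n_estimators))
        best = max(self.reports_,
                   key=lambda r: (r.test_acc, -r.n_genes))
        self.best_report_ = best
        tr = [s for s in X_top.index if s in set(split.train_samples)]
        Xtr = X_top.loc[tr, list(best.best_panel)].to_numpy(dtype=float)
        self._mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        self._sd = sd
        self.best_model_ = make_classifier(
            best.classifier, self.random_state, self.n_estimators
        ) if best.classifier in CLASSIFIER_NAMES else clone(best.classifier)
        self.best_model_.fit((Xtr - self._mu) / self._sd, labels.loc[tr].to_numpy())
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xp = X[list(self.best_report_.best_panel)].to_numpy(dtype=float)
        return self.best_model_.predict((Xp - self._mu) / self._sd)

    def report_frame(self) -> pd.DataFrame:
        return reports_to_frame(self.reports_)
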