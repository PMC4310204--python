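"""Feature subset selection: information gain, SVM-RFE, and the
backtracking variant (B-SVM-RFE).

SVM-RFE ranks features by the squared weight they receive in a
linear-kernel SVM, repeatedly eliminating the lowest-weight feature.
The backtracking variant consults the per-feature information gain:
when an eliminated feature's gain exceeds the lowest gain still in the
surviving set, the highest-gain eliminated feature is provisionally
re-admitted and kept only if the cross-validated error strictly
improves.  Subset quality is reported as the 5-fold cross-validation
error with default SVM parameters (LooErrorRate) and the error on an
independent test set after a grid search (TestErrorRate), both in
percent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


@dataclass
class LabeledDataset:
    """Feature matrix with {+1, -1} labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y have incompatible shapes")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("labels must be in {+1, -1}")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length mismatch")

    @classmethod
    def from_dataframe(cls, df, label_col: str = "label") -> "LabeledDataset":
        y = df[label_col].to_numpy(dtype=int)
        X = df.drop(columns=[label_col])
        return cls(X=X.to_numpy(dtype=float), y=y, feature_names=tuple(X.columns))

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def entropy(labels) -> float:
    """Shannon entropy of the label distribution, in bits."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty label set is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def info_gain(feature_column, labels) -> float:
    """Information gain of a continuous feature for binary labels.

    The feature is discretised by the single threshold maximising the
    gain (all midpoints between consecutive distinct sorted values are
    scanned); the maximum gain is returned.  A constant column yields 0.
    """
    gain, _ = info_gain_with_threshold(feature_column, labels)
    return gain


def info_gain_with_threshold(feature_column, labels) -> tuple:
    x = np.asarray(feature_column, dtype=float)
    y = np.asarray(labels)
    n = x.size
    if n == 0:
        raise ValueError("empty column")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    classes = np.unique(ys)
    h_c = entropy(ys)
    if classes.size < 2 or xs[0] == xs[-1]:
        return 0.0, None

    # cumulative class counts below each cut point k (split: first k vs rest)
    onehot = (ys[:, None] == classes[None, :]).astype(float)
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]
    boundaries = np.nonzero(np.diff(xs) > 0)[0]  # cut after index k
    best_gain, best_thr = 0.0, None
    for k in boundaries:
        left = cum[k]
        right = total - left
        nl, nr = left.sum(), right.sum()

        def h(counts, m):
            p = counts[counts > 0] / m
            return float(-(p * np.log2(p)).sum())

        cond = (nl / n) * h(left, nl) + (nr / n) * h(right, nr)
        gain = h_c - cond
        if gain > best_gain:
            best_gain = gain
            best_thr = (xs[k] + xs[k + 1]) / 2
    return best_gain, best_thr


@dataclass
class IGTable:
    """Per-feature information gain and induced threshold."""

    gains: np.ndarray
    thresholds: tuple
    feature_names: tuple

    @classmethod
    def from_dataset(cls, dataset: LabeledDataset) -> "IGTable":
        gains, thresholds = [], []
        for j in range(dataset.n_features):
            g, t = info_gain_with_threshold(dataset.X[:, j], dataset.y)
            gains.append(g)
            thresholds.append(t)
        return cls(
            gains=np.array(gains), thresholds=tuple(thresholds), feature_names=dataset.feature_names
        )


@dataclass
class RfeRanking:
    """Elimination order (first-eliminated last in `order`... the list is
    stored best-first: order[0] survived longest) and per-step weights."""

    order: list
    criteria_trace: list = field(default_factory=list)


def _check_trainable(dataset: LabeledDataset) -> None:
    pos = int((dataset.y == 1).sum())
    neg = int((dataset.y == -1).sum())
    if pos < 2 or neg < 2:
        raise ValueError("need at least 2 samples per class")


def svm_rfe(dataset: LabeledDataset, C: float = 1.0) -> RfeRanking:
    """Recursive feature elimination with a linear-kernel SVM.

    Each round trains on the surviving features, scores c_i = w_i^2 and
    removes the argmin (ties broken by lowest feature index), prepending
    it to the ranked list.  Returns the full ranking.
    """
    _check_trainable(dataset)
    s = list(range(dataset.n_features))
    r: list = []
    trace: list = []
    while s:
        if len(s) == 1:
            r.insert(0, s.pop())
            break
        clf = SVC(kernel="linear", C=C)
        clf.fit(dataset.X[:, s], dataset.y)
        c = np.asarray(clf.coef_).ravel() ** 2
        f = int(np.argmin(c))  # argmin takes the lowest index on ties
        trace.append((tuple(s), tuple(c)))
        r.insert(0, s.pop(f))
    return RfeRanking(order=r, criteria_trace=trace)


@dataclass
class SelectionResult:
    """Outcome of a selection run: surviving subset plus the evaluation
    trace of every visited subset size."""

    selected: tuple  # feature indices
    selected_names: tuple
    trace: list  # (size, loo_error_pct, test_error_pct | None)
    seed: int = 0

    def to_json(self, path) -> None:
        payload = {
            "selected": list(self.selected),
            "selected_names": list(self.selected_names),
            "seed": self.seed,
            "trace": [
                {"size": s, "LooErrorRate": lo, "TestErrorRate": te}
                for s, lo, te in self.trace
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            selected=tuple(p["selected"]),
            selected_names=tuple(p["selected_names"]),
            trace=[(t["size"], t["LooErrorRate"], t["TestErrorRate"]) for t in p["trace"]],
            seed=p["seed"],
        )


def _cv_error_pct(
    X: np.ndarray, y: np.ndarray, cv_folds: int, seed: int
) -> float:
    """5-fold CV error (percent) with default C and gamma."""
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    acc = cross_val_score(SVC(kernel="rbf"), X, y, cv=cv).mean()
    return float((1.0 - acc) * 100.0)


def b_svm_rfe(
    dataset: LabeledDataset,
    ig: Optional[IGTable] = None,
    cv_folds: int = 5,
    seed: int = 0,
    test: Optional[LabeledDataset] = None,
    C: float = 1.0,
) -> SelectionResult:
    """SVM-RFE with information-gain backtracking.

    After each elimination, if some eliminated feature has higher gain
    than the minimum-gain survivor, the highest-gain eliminated feature
    is provisionally re-admitted; the re-admission is kept iff the
    cross-validated error strictly improves on the current subset's.
    Each feature is re-admitted at most once, which guarantees
    termination.  The returned subset is the visited subset with the
    best evaluation (lowest TestErrorRate when a test set is supplied,
    ties broken by LooErrorRate, then by smaller size).
    """
    _check_trainable(dataset)
    if ig is None:
        ig = IGTable.from_dataset(dataset)
    gains = ig.gains

    s = list(range(dataset.n_features))
    r: list = []
    readmitted: set = set()
    visited: list = []  # (subset tuple, loo_error)

    def loo(subset: Sequence[int]) -> float:
        return _cv_error_pct(dataset.X[:, list(subset)], dataset.y, cv_folds, seed)

    current_err = loo(s)
    visited.append((tuple(s), current_err))

    while len(s) > 1:
        clf = SVC(kernel="linear", C=C)
        clf.fit(dataset.X[:, s], dataset.y)
        c = np.asarray(clf.coef_).ravel() ** 2
        r.insert(0, s.pop(int(np.argmin(c))))

        current_err = loo(s)
        visited.append((tuple(s), current_err))

        # backtracking: consult information gain
        if r and s:
            min_gain_s = gains[s].min()
            candidates = [f for f in r if gains[f] > min_gain_s and f not in readmitted]
            if candidates:
                cand = max(candidates, key=lambda f: gains[f])
                trial = sorted(s + [cand])
                trial_err = loo(trial)
                if trial_err < current_err:
                    s.append(cand)
                    r.remove(cand)
                    readmitted.add(cand)
                    current_err = trial_err
                    visited.append((tuple(sorted(s)), current_err))
    if s:
        r.insert(0, s.pop())

    # evaluate the trace, optionally against an independent test set
    trace: list = []
    best = None
    for subset, loo_err in visited:
        test_err = None
        if test is not None:
            _, test_err = evaluate_subset(dataset, test, subset, cv_folds=cv_folds, seed=seed)
        trace.append((len(subset), loo_err, test_err))
        key = (
            (test_err, loo_err, len(subset)) if test is not None else (loo_err, len(subset))
        )
        if best is None or key < best[0]:
            best = (key, subset)

    selected = tuple(best[1])
    return SelectionResult(
        selected=selected,
        selected_names=tuple(dataset.feature_names[i] for i in selected),
        trace=trace,
        seed=seed,
    )


DEFAULT_C_GRID = tuple(2.0 ** k for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** k for k in range(-15, 4, 2))


def grid_search_svm(
    X: np.ndarray,
    y: np.ndarray,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    cv_folds: int = 5,
    seed: int = 0,
) -> SVC:
    from sklearn.model_selection import GridSearchCV

    if not c_grid or not gamma_grid:
        raise ValueError("empty parameter grid")
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(
        SVC(kernel="rbf"), {"C": list(c_grid), "gamma": list(gamma_grid)}, cv=cv, n_jobs=1
    )
    gs.fit(X, y)
    return gs.best_estimator_


def evaluate_subset(
    train: LabeledDataset,
    test: LabeledDataset,
    subset: Sequence[int],
    cv_folds: int = 5,
    seed: int = 0,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
) -> tuple:
    """(LooErrorRate %, TestErrorRate %) for a feature subset.

    LooErrorRate: stratified `cv_folds`-fold CV error on the training
    set with default SVM parameters.  TestErrorRate: error on the
    independent test set after a grid search for (C, gamma) on the
    training set.  Train and test must be disjoint sample sets.
    """
    train_rows = {row.tobytes() for row in train.X}
    if any(row.tobytes() in train_rows for row in test.X):
        raise ValueError("train and test sets overlap")
    cols = list(subset)
    loo = _cv_error_pct(train.X[:, cols], train.y, cv_folds, seed)
    clf = grid_search_svm(
        train.X[:, cols], train.y, c_grid=c_grid, gamma_grid=gamma_grid,
        cv_folds=cv_folds, seed=seed,
    )
    acc = float((clf.predict(test.X[:, cols]) == test.y).mean())
    return loo, float((1.0 - acc) * 100.0)
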