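"""SVM classifier stack: SMOTE rebalancing, grid-searched RBF-SVM
training, evaluation metrics, and the integrated two-stage predictor
(precursor stage + mature-locating stage).

The two-stage predictor first classifies a candidate hairpin as a real
or pseudo precursor; for precursor-positives it enumerates
pairing-closed sub-segments, classifies each with the mature-stage
model, and reports the terminal 21 nt of the best-scoring positive
segment as the located mature miRNA.

A statsmodels-flavoured front end is provided by
:class:`PrecursorClassifier` (built from a labelled feature DataFrame;
``fit()`` returns a :class:`PrecursorClassifierResults` carrying the
trained model, the selection trace, cross-validated metrics and a
``summary()`` table).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .features import (
    FeatureConfig,
    FeatureScaler,
    FEATURE_NAMES,
    apply_scaler,
    extract_all,
    fit_scaler,
)
from .hairpin import HairpinRecord, engine_version, is_single_stem_loop
from .datasets import MIN_SEGMENT_LEN, close_under_pairing
from .selection import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    LabeledDataset,
    SelectionResult,
    b_svm_rfe,
    grid_search_svm,
)


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

@dataclass
class SmoteConfig:
    """Oversampling multiplier N (minority grows to N x original), k
    nearest neighbours, and the RNG seed."""

    ratio: int = 2
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio < 1 or self.k < 1:
            raise ValueError("ratio and k must be >= 1")


def smote(minority: np.ndarray, config: SmoteConfig) -> np.ndarray:
    """Synthetic minority oversampling.

    Emits (ratio - 1) * n synthetic samples, each x + rand*(y - x) for a
    random one y of x's k nearest neighbours (Euclidean) and
    rand in [0, 1).  Every synthetic point therefore lies on the segment
    between a minority sample and one of its neighbours.
    """
    X = np.asarray(minority, dtype=float)
    n = X.shape[0]
    if n <= config.k:
        raise ValueError(f"SMOTE needs more than k={config.k} minority samples, got {n}")
    n_new = (config.ratio - 1) * n
    if n_new == 0:
        return np.empty((0, X.shape[1]))
    nn = NearestNeighbors(n_neighbors=config.k + 1).fit(X)
    _, idx = nn.kneighbors(X)  # column 0 is the point itself
    rng = np.random.default_rng(config.seed)
    base = rng.integers(0, n, size=n_new)
    pick = rng.integers(1, config.k + 1, size=n_new)
    rand = rng.random(size=(n_new, 1))
    neigh = idx[base, pick]
    return X[base] + rand * (X[neigh] - X[base])


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metrics:
    """Confusion counts and the derived proportions SE, SP, Acc, Gm, FPR."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def SE(self) -> float:
        d = self.TP + self.FN
        return self.TP / d if d else 0.0

    @property
    def SP(self) -> float:
        d = self.FP + self.TN
        return self.TN / d if d else 0.0

    @property
    def Acc(self) -> float:
        total = self.TP + self.FP + self.TN + self.FN
        return (self.TP + self.TN) / total if total else 0.0

    @property
    def Gm(self) -> float:
        return math.sqrt(self.SE * self.SP)

    @property
    def FPR(self) -> float:
        return 1.0 - self.SP

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "Metrics":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.size == 0:
            raise ValueError("cannot evaluate on an empty dataset")
        return cls(
            TP=int(((y_true == 1) & (y_pred == 1)).sum()),
            FP=int(((y_true == -1) & (y_pred == 1)).sum()),
            TN=int(((y_true == -1) & (y_pred == -1)).sum()),
            FN=int(((y_true == 1) & (y_pred == -1)).sum()),
        )


# ---------------------------------------------------------------------------
# SVM training
# ---------------------------------------------------------------------------

@dataclass
class SvmModel:
    """A trained RBF-SVM stage: estimator + scaler + feature subset."""

    estimator: SVC
    scaler: FeatureScaler
    feature_subset: tuple  # names, in order
    seed: int = 0
    engine: str = ""

    def _design(self, features) -> np.ndarray:
        import pandas as pd

        if isinstance(features, pd.DataFrame):
            scaled = apply_scaler(self.scaler, features[list(self.scaler.names)])
            return scaled[list(self.feature_subset)].to_numpy()
        raise TypeError("expected a feature DataFrame with named columns")

    def predict(self, features) -> np.ndarray:
        return self.estimator.predict(self._design(features))

    def decision_value(self, features) -> np.ndarray:
        return self.estimator.decision_function(self._design(features))

    def evaluate(self, features, y_true) -> Metrics:
        return Metrics.from_predictions(y_true, self.predict(features))


def train_svm(
    dataset: LabeledDataset,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    cv_folds: int = 5,
    seed: int = 0,
    scaler: Optional[FeatureScaler] = None,
) -> SvmModel:
    """Grid-search (C, gamma) by stratified CV accuracy, refit on all data.

    The dataset is expected pre-scaled (fit a scaler first and pass it
    for bookkeeping); deterministic for a fixed seed.
    """
    if len(set(np.unique(dataset.y))) < 2:
        raise ValueError("training requires both classes")
    est = grid_search_svm(
        dataset.X, dataset.y, c_grid=c_grid, gamma_grid=gamma_grid,
        cv_folds=cv_folds, seed=seed,
    )
    if scaler is None:
        scaler = FeatureScaler(
            names=dataset.feature_names,
            min_=np.full(dataset.n_features, -1.0),
            max_=np.full(dataset.n_features, 1.0),
        )
    try:
        engine = engine_version()
    except Exception:
        engine = "unavailable"
    return SvmModel(
        estimator=est,
        scaler=scaler,
        feature_subset=tuple(dataset.feature_names),
        seed=seed,
        engine=engine,
    )


def evaluate(model: SvmModel, dataset: LabeledDataset) -> Metrics:
    if dataset.X.shape[0] == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    return Metrics.from_predictions(dataset.y, model.estimator.predict(dataset.X))


# ---------------------------------------------------------------------------
# Two-stage predictor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Verdict:
    """Outcome of two-stage prediction on one candidate hairpin."""

    kind: str  # reject_pre | pre_only | miRNA_located
    stage1_score: float = 0.0
    mir_interval: Optional[tuple] = None
    segment_interval: Optional[tuple] = None
    reason: str = ""


@dataclass
class TwoStageModel:
    """Precursor-stage + mature-stage SVMs with the segment policy."""

    pre_stage: SvmModel
    mat_stage: SvmModel
    segment_stride: int = 5

    def predict(
        self,
        candidate: HairpinRecord,
        config: Optional[FeatureConfig] = None,
        temperature: float = 37.0,
    ) -> Verdict:
        return predict_two_stage(self, candidate, config=config, temperature=temperature)

    def save(self, directory) -> None:
        import joblib

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "segment_stride": self.segment_stride,
            "pre_subset": list(self.pre_stage.feature_subset),
            "mat_subset": list(self.mat_stage.feature_subset),
            "pre_seed": self.pre_stage.seed,
            "mat_seed": self.mat_stage.seed,
            "engine": self.pre_stage.engine,
        }
        (d / "metadata.json").write_text(json.dumps(meta, indent=1))
        self.pre_stage.scaler.to_json(d / "pre_scaler.json")
        self.mat_stage.scaler.to_json(d / "mat_scaler.json")
        joblib.dump(self.pre_stage.estimator, d / "pre_stage.joblib")
        joblib.dump(self.mat_stage.estimator, d / "mat_stage.joblib")

    @classmethod
    def load(cls, directory) -> "TwoStageModel":
        import joblib

        d = Path(directory)
        meta = json.loads((d / "metadata.json").read_text())
        pre = SvmModel(
            estimator=joblib.load(d / "pre_stage.joblib"),
            scaler=FeatureScaler.from_json(d / "pre_scaler.json"),
            feature_subset=tuple(meta["pre_subset"]),
            seed=meta["pre_seed"],
            engine=meta["engine"],
        )
        mat = SvmModel(
            estimator=joblib.load(d / "mat_stage.joblib"),
            scaler=FeatureScaler.from_json(d / "mat_scaler.json"),
            feature_subset=tuple(meta["mat_subset"]),
            seed=meta["mat_seed"],
            engine=meta["engine"],
        )
        return cls(pre_stage=pre, mat_stage=mat, segment_stride=meta["segment_stride"])


def _features_frame(record: HairpinRecord, config: FeatureConfig):
    import pandas as pd

    vec = extract_all(record, config)
    return pd.DataFrame([vec.values], index=[vec.source_id], columns=list(FEATURE_NAMES))


def enumerate_segments(record: HairpinRecord, stride: int = 5) -> List[tuple]:
    """Candidate mature-stage segments: pairing-closed intervals longer
    than 55 nt, enumerated on a stride grid and deduplicated."""
    L = len(record)
    seen = set()
    out = []
    for a in range(0, max(1, L - MIN_SEGMENT_LEN + 1), stride):
        for b in range(min(L, a + MIN_SEGMENT_LEN), L + 1, stride):
            iv = close_under_pairing(record, (a, b))
            if iv[1] - iv[0] >= MIN_SEGMENT_LEN and iv not in seen:
                seen.add(iv)
                out.append(iv)
    return out


def predict_two_stage(
    model: TwoStageModel,
    candidate: HairpinRecord,
    config: Optional[FeatureConfig] = None,
    temperature: float = 37.0,
) -> Verdict:
    """Run the integrated classifier on one folded candidate.

    Stage 1 scores the whole hairpin; non-hairpin inputs are rejected
    outright.  For stage-1 positives every enumerated sub-segment is
    refolded and scored by stage 2; the best positive segment's
    3'-terminal 21 nt (ties: highest decision value, then 5'-most
    segment) is reported as the located miRNA, in precursor coordinates.
    """
    config = config or FeatureConfig(shuffles=8)
    if not is_single_stem_loop(candidate.annotation):
        return Verdict(kind="reject_pre", reason="not a single stem-loop")
    feats = _features_frame(candidate, config)
    score = float(model.pre_stage.decision_value(feats)[0])
    if model.pre_stage.predict(feats)[0] != 1:
        return Verdict(kind="reject_pre", stage1_score=score, reason="stage-1 negative")

    best: Optional[tuple] = None  # (decision, -start, interval)
    for iv in enumerate_segments(candidate, model.segment_stride):
        sub = candidate.sequence.subsequence(iv[0], iv[1], id=f"{candidate.id}|{iv[0]}-{iv[1]}")
        seg = HairpinRecord.from_sequence(sub, temperature=temperature, with_partition=True)
        sf = _features_frame(seg, config)
        if model.mat_stage.predict(sf)[0] == 1:
            dv = float(model.mat_stage.decision_value(sf)[0])
            key = (dv, -iv[0])
            if best is None or key > best[0]:
                best = (key, iv)
    if best is None:
        return Verdict(kind="pre_only", stage1_score=score)
    iv = best[1]
    mir = (max(iv[0], iv[1] - 21), iv[1])
    return Verdict(
        kind="miRNA_located", stage1_score=score, mir_interval=mir, segment_interval=iv
    )


# ---------------------------------------------------------------------------
# Model / Results front end
# ---------------------------------------------------------------------------

class PrecursorClassifier:
    """Real-vs-pseudo hairpin classifier built from a labelled feature table.

    Parameters
    ----------
    data : LabeledDataset or pandas.DataFrame
        152-column (or subset) feature matrix with labels in {+1, -1}.
        DataFrames must carry the labels in `label_col`.
    """

    def __init__(self, data, label_col: str = "label"):
        if isinstance(data, LabeledDataset):
            self.dataset = data
        else:
            self.dataset = LabeledDataset.from_dataframe(data, label_col=label_col)

    @classmethod
    def from_dataframe(cls, df, label_col: str = "label") -> "PrecursorClassifier":
        return cls(df, label_col=label_col)

    def fit(
        self,
        select: bool = True,
        smote_ratio: int = 1,
        cv_folds: int = 5,
        seed: int = 0,
        c_grid: Sequence[float] = DEFAULT_C_GRID,
        gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    ) -> "PrecursorClassifierResults":
        """Scale to [-1, 1], optionally rebalance with SMOTE and select
        features with B-SVM-RFE, then grid-search and train the SVM."""
        ds = self.dataset
        scaler = fit_scaler(ds.X, names=ds.feature_names)
        X = scaler.transform(ds.X)
        y = ds.y
        if smote_ratio > 1:
            minority_label = 1 if (y == 1).sum() < (y == -1).sum() else -1
            syn = smote(
                X[y == minority_label], SmoteConfig(ratio=smote_ratio, seed=seed)
            )
            X = np.vstack([X, syn])
            y = np.concatenate([y, np.full(len(syn), minority_label)])
        scaled = LabeledDataset(X=X, y=y, feature_names=ds.feature_names)
        selection = None
        subset = tuple(range(ds.n_features))
        if select:
            selection = b_svm_rfe(scaled, cv_folds=cv_folds, seed=seed)
            subset = selection.selected
        sub_ds = LabeledDataset(
            X=X[:, list(subset)],
            y=y,
            feature_names=tuple(ds.feature_names[i] for i in subset),
        )
        model = train_svm(
            sub_ds, c_grid=c_grid, gamma_grid=gamma_grid, cv_folds=cv_folds,
            seed=seed, scaler=scaler,
        )
        train_metrics = evaluate(model, sub_ds)
        return PrecursorClassifierResults(
            model=model, selection=selection, train_metrics=train_metrics, seed=seed
        )


@dataclass
class PrecursorClassifierResults:
    """Fitted precursor classifier: trained stage, selection trace and
    resubstitution metrics; `evaluate` scores an independent test set."""

    model: SvmModel
    selection: Optional[SelectionResult]
    train_metrics: Metrics
    seed: int

    def predict(self, features) -> np.ndarray:
        return self.model.predict(features)

    def evaluate(self, features, y_true) -> Metrics:
        return self.model.evaluate(features, y_true)

    def summary(self) -> str:
        m = self.train_metrics
        est = self.model.estimator
        lines = [
            "Precursor classifier (RBF-SVM)",
            "=" * 46,
            f"features used        {len(self.model.feature_subset):>10d}",
            f"C                    {est.C:>10.4g}",
            f"gamma                {float(est.gamma):>10.4g}",
            f"training SE          {m.SE:>10.4f}",
            f"training SP          {m.SP:>10.4f}",
            f"training Acc         {m.Acc:>10.4f}",
            f"training Gm          {m.Gm:>10.4f}",
            f"seed                 {self.seed:>10d}",
        ]
        if self.selection is not None:
            best = min(self.selection.trace, key=lambda t: (t[1], t[0]))
            lines.append(f"selection trace best {best[1]:>9.2f}% CV error @ {best[0]} features")
        return "\n".join(lines)
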