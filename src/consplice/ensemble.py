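"""Ensemble classifier combining regional constraint with per-nucleotide
splice predictions.

The feature vector per variant is [regional constraint score, max
splice-prediction delta score, max spliceosome-classifier score]; a Random
Forest of 1000 trees votes a pathogenicity probability in [0, 1]. Training
splits are grouped by constraint region so that no region contributes
variants to both sides, and cross-validation is class-stratified.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupShuffleSplit, StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .constraint import SplicingConstraintModel
from .evaluation import PRCurve, average_precision, pr_curve
from .genome import AUTOSOME, GenomeConfig

FEATURE_ORDER = ("constraint", "spliceai_max", "squirls_max")
DEFAULT_N_TREES = 1000
#: Recommended preliminary decision threshold on the pathogenicity probability.
DEFAULT_THRESHOLD = 0.5
MODEL_FORMAT_VERSION = 1


def assemble_examples(
    truth: pd.DataFrame,
    model: SplicingConstraintModel,
    genome: GenomeConfig,
    spliceai_feature: str = "max",
) -> pd.DataFrame:
    """Labeled feature vectors for truth-set variants.

    Keeps autosomal variants that have a constraint score (i.e. fall in a
    retained region), finite splice-prediction deltas, and a spliceosome
    score. ``spliceai_feature`` selects max-of-four deltas (default) or their
    sum as the splice-prediction feature. Attaches the covering region id for
    group-aware splitting.
    """
    if spliceai_feature not in ("max", "sum"):
        raise ValueError("spliceai_feature must be 'max' or 'sum'")
    df = truth.copy()
    df = df[[genome.chromosome_class(c) == AUTOSOME for c in df["chrom"]]]
    deltas = df[["spliceai_ag", "spliceai_al", "spliceai_dg", "spliceai_dl"]].to_numpy(dtype=float)
    df["spliceai_max"] = deltas.max(axis=1) if spliceai_feature == "max" else np.minimum(deltas.sum(axis=1), 1.0)
    df["constraint"] = [
        model.score_position(c, int(p)) for c, p in zip(df["chrom"], df["pos"])
    ]
    df["region_id"] = [
        model.region_id_at(c, int(p)) for c, p in zip(df["chrom"], df["pos"])
    ]
    feats = df[list(FEATURE_ORDER)].to_numpy(dtype=float)
    keep = np.isfinite(feats).all(axis=1) & df["region_id"].notna().to_numpy()
    out = df[keep].reset_index(drop=True)
    classes = set(out["label"].unique())
    if classes != {"pathogenic", "benign"}:
        raise ValueError(f"need both classes after assembly, got {sorted(classes)}")
    return out


def group_split(
    examples: pd.DataFrame,
    train_fraction: float = 0.6,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train/test split keeping each constraint region wholly on one side."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    groups = examples["region_id"].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("all examples share one constraint region; cannot split")
    splitter = GroupShuffleSplit(n_splits=1, train_size=train_fraction, random_state=seed)
    train_idx, test_idx = next(splitter.split(examples, groups=groups))
    return (
        examples.iloc[np.sort(train_idx)].reset_index(drop=True),
        examples.iloc[np.sort(test_idx)].reset_index(drop=True),
    )


class ConSpliceML(ClassifierMixin, BaseEstimator):
    """Random Forest over [constraint, splice-prediction max, spliceosome max].

    Probabilities are the forest's vote fraction for the pathogenic class;
    ``predict`` applies the recommended 0.5 cutoff. Fully reproducible under
    ``random_state``.
    """

    def __init__(self, n_trees: int = DEFAULT_N_TREES, random_state: int = 0):
        self.n_trees = n_trees
        self.random_state = random_state

    @staticmethod
    def _matrix(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = set(FEATURE_ORDER) - set(X.columns)
            if missing:
                raise ValueError(f"feature columns missing: {sorted(missing)}")
            X = X[list(FEATURE_ORDER)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(FEATURE_ORDER):
            raise ValueError(f"expected features in order {FEATURE_ORDER}")
        if not np.isfinite(X).all():
            raise ValueError("features must be finite")
        return X

    @staticmethod
    def _labels(y) -> np.ndarray:
        arr = np.asarray(y)
        if arr.dtype.kind in "bif":
            return arr.astype(int)
        return (arr == "pathogenic").astype(int)

    def fit(self, X, y):
        Xm = self._matrix(X)
        ym = self._labels(y)
        if len(np.unique(ym)) < 2:
            raise ValueError("both classes are required to train the ensemble")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.random_state, n_jobs=1
        )
        self.forest_.fit(Xm, ym)
        self.feature_order_ = FEATURE_ORDER
        self.classes_ = self.forest_.classes_
        self.fingerprint_ = hashlib.sha256(
            Xm.tobytes() + ym.tobytes() + str(self.random_state).encode()
        ).hexdigest()
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(self._matrix(X))

    def predict_pathogenic(self, X) -> np.ndarray:
        """Probability that each variant is a pathogenic splice-altering variant."""
        proba = self.predict_proba(X)
        return proba[:, list(self.forest_.classes_).index(1)]

    def predict(self, X) -> np.ndarray:
        return (self.predict_pathogenic(X) >= DEFAULT_THRESHOLD).astype(int)


@dataclass
class CVResult:
    curves: list[PRCurve]
    fold_average_precision: list[float]
    pooled_average_precision: float


def cross_validate(
    train: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> CVResult:
    """Class-stratified k-fold CV on the training set.

    Each fold holds out a distinct, class-balanced 1/k of the examples; a
    forest trained on the remainder scores it. Returns per-fold PR curves
    plus the pooled (all held-out predictions combined) average precision.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = ConSpliceML._labels(train["label"])
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError("too few examples of one class to stratify the folds")
    X = train[list(FEATURE_ORDER)].to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    curves, aps = [], []
    pooled_scores = np.empty(len(y))
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        clf = ConSpliceML(n_trees=n_trees, random_state=seed + fold).fit(X[tr], y[tr])
        scores = clf.predict_pathogenic(X[va])
        pooled_scores[va] = scores
        curve = pr_curve(scores, y[va])
        curves.append(curve)
        aps.append(average_precision(curve))
    pooled = average_precision(pr_curve(pooled_scores, y))
    return CVResult(curves=curves, fold_average_precision=aps, pooled_average_precision=pooled)


def save_model(model: ConSpliceML, path) -> None:
    check_is_fitted(model, "forest_")
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "n_trees": model.n_trees,
            "random_state": model.random_state,
            "feature_order": list(model.feature_order_),
            "fingerprint": model.fingerprint_,
            "forest": model.forest_,
        },
        path,
    )


def load_model(path) -> ConSpliceML:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupted or not a model file
        raise ValueError(f"cannot load ensemble model from {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format in {path}; expected version {MODEL_FORMAT_VERSION}"
        )
    model = ConSpliceML(n_trees=payload["n_trees"], random_state=payload["random_state"])
    model.forest_ = payload["forest"]
    model.feature_order_ = tuple(payload["feature_order"])
    model.classes_ = model.forest_.classes_
    model.fingerprint_ = payload["fingerprint"]
    return model
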