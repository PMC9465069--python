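"""Random-forest classification of contigs, with organism-grouped
stratified cross-validation.

The model is a 100-tree random forest with class weights inversely
proportional to class frequencies ("balanced"), trained on the
gene-structure feature matrix.  Cross-validation assigns whole organisms
to folds (no contig of one genome may sit in both train and test) while
stratifying class proportions — sklearn's ``StratifiedGroupKFold``.
Group integrity is asserted on every run, not only in tests.

Two variants exist: *standard* (8 gene-structure features) and
*with_tiara* (plus the encoded external k-mer call).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, precision_score, recall_score
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.utils.validation import check_is_fitted

from .exceptions import (
    ModelFormatError,
    ModelVersionError,
    ParameterError,
    SchemaError,
)
from .features import TIARA_FEATURE, model_matrix
from .types import CLASS_LABELS, EUKARYOTE, PROKARYOTE

MODEL_SCHEMA_VERSION = "karyon-model-1"

VARIANT_STANDARD = "standard"
VARIANT_WITH_TIARA = "with_tiara"


def _check_matrix(X: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise SchemaError("feature matrix must be a pandas DataFrame")
    X = model_matrix(X)
    if X.shape[1] == 0:
        raise SchemaError("no model feature columns present in the matrix")
    bad = X.index[X.isna().any(axis=1)]
    if len(bad):
        raise ParameterError(
            f"NaN feature values in rows: {list(map(str, bad[:10]))}"
        )
    return X


class ContigRandomForest(ClassifierMixin, BaseEstimator):
    """Random forest over gene-structure features, scikit-learn style.

    Parameters
    ----------
    n_estimators : int, default 100
        Number of trees.
    class_weight : str or None, default "balanced"
        Per-class sample weights; "balanced" compensates class imbalance.
    random_state : int or None
        Seed; fixes tree construction (and hence predictions) exactly.

    Attributes (after fit)
    ----------------------
    feature_names_ : list of str — column schema the model expects.
    classes_ : ndarray — the two class labels.
    importances_ : ndarray — mean-decrease-in-impurity importances, sum 1.
    variant_ : "standard" or "with_tiara".

    At a 50/50 vote-share tie the predicted class is prokaryote: the
    default downstream consumers are prokaryote pipelines, and with 100
    trees exact ties are rare.
    """

    def __init__(
        self,
        n_estimators: int = 100,
        class_weight: Optional[str] = "balanced",
        random_state: Optional[int] = None,
        n_jobs: Optional[int] = None,
    ) -> None:
        self.n_estimators = n_estimators
        self.class_weight = class_weight
        self.random_state = random_state
        self.n_jobs = n_jobs

    def fit(self, X: pd.DataFrame, y: Sequence[str]) -> "ContigRandomForest":
        X = _check_matrix(X)
        y = np.asarray(y, dtype=object)
        present = set(y)
        if len(present) < 2:
            raise ParameterError(
                f"training data contains a single class: {sorted(present)}"
            )
        unknown = present - set(CLASS_LABELS)
        if unknown:
            raise ParameterError(f"unknown class labels: {sorted(unknown)}")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            class_weight=self.class_weight,
            random_state=self.random_state,
            n_jobs=self.n_jobs,
        )
        self.forest_.fit(X.to_numpy(dtype=float), y)
        self.feature_names_ = list(X.columns)
        self.classes_ = self.forest_.classes_
        imp = self.forest_.feature_importances_
        self.importances_ = imp / imp.sum()
        self.variant_ = (
            VARIANT_WITH_TIARA if TIARA_FEATURE in self.feature_names_ else VARIANT_STANDARD
        )
        return self

    def _validate_schema(self, X: pd.DataFrame) -> pd.DataFrame:
        X = model_matrix(X)
        got, want = list(X.columns), self.feature_names_
        if got != want:
            missing = [c for c in want if c not in got]
            extra = [c for c in got if c not in want]
            parts = []
            if missing:
                parts.append(f"missing: {missing}")
            if extra:
                parts.append(f"extra: {extra}")
            if not missing and not extra:
                parts.append(f"misordered: got {got}, expected {want}")
            raise SchemaError("feature schema mismatch — " + "; ".join(parts))
        return X

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "forest_")
        X = self._validate_schema(_check_matrix(X))
        if len(X) == 0:
            return np.empty((0, len(self.classes_)))
        return self.forest_.predict_proba(X.to_numpy(dtype=float))

    @staticmethod
    def _labels_from_proba(proba: np.ndarray, classes: np.ndarray) -> np.ndarray:
        """Eukaryote only on a strict majority of tree votes; ties go to
        prokaryote."""
        euk_idx = int(np.where(classes == EUKARYOTE)[0][0])
        return np.where(proba[:, euk_idx] > 0.5, EUKARYOTE, PROKARYOTE)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        proba = self.predict_proba(X)
        return self._labels_from_proba(proba, self.classes_)

    def vote_shares(self, X: pd.DataFrame) -> pd.DataFrame:
        """Predicted class and its vote share, indexed like ``X``."""
        proba = self.predict_proba(X)
        labels = self._labels_from_proba(proba, self.classes_)
        share = proba[np.arange(len(labels)), [list(self.classes_).index(l) for l in labels]] if len(labels) else np.empty(0)
        return pd.DataFrame(
            {"predicted_class": labels, "vote_share": share},
            index=model_matrix(X).index,
        )

    def feature_importance_report(self) -> list[tuple[str, float]]:
        """(feature, importance) sorted by decreasing importance; ties keep
        the frozen feature order."""
        check_is_fitted(self, "forest_")
        pairs = list(zip(self.feature_names_, self.importances_))
        return sorted(pairs, key=lambda t: -t[1])


@dataclass
class TrainedModel:
    """A fitted forest plus the metadata needed to apply it safely."""

    forest: ContigRandomForest
    feature_names: list[str]
    class_labels: tuple[str, ...]
    importances: np.ndarray
    variant: str
    training_seed: Optional[int]
    schema_version: str = MODEL_SCHEMA_VERSION


def train(
    features: pd.DataFrame, labels: Sequence[str], seed: Optional[int] = None
) -> TrainedModel:
    """Fit the 100-tree balanced forest on a full feature matrix."""
    est = ContigRandomForest(random_state=seed).fit(features, labels)
    return TrainedModel(
        forest=est,
        feature_names=est.feature_names_,
        class_labels=tuple(est.classes_),
        importances=est.importances_,
        variant=est.variant_,
        training_seed=seed,
    )


def predict(
    model: TrainedModel, features: pd.DataFrame
) -> list[tuple[str, str, float]]:
    """Apply a trained model: (contig_id, predicted class, vote share)."""
    shares = model.forest.vote_shares(features)
    return [
        (str(cid), row.predicted_class, float(row.vote_share))
        for cid, row in shares.iterrows()
    ]


def feature_importance_report(model: TrainedModel) -> list[tuple[str, float]]:
    return model.forest.feature_importance_report()


@dataclass
class CVReport:
    """Per-fold metrics of organism-grouped stratified cross-validation.

    Precision and recall are reported with eukaryote as the positive
    class (prokaryote-positive values are kept alongside, as is the
    macro average).
    """

    n_folds: int
    accuracy: np.ndarray
    precision_eukaryote: np.ndarray
    recall_eukaryote: np.ndarray
    precision_prokaryote: np.ndarray
    recall_prokaryote: np.ndarray
    fold_assignments: dict[str, int]
    group_integrity: bool
    fold_class_proportions: list[float] = field(default_factory=list)
    global_class_proportion: float = 0.0

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracy.mean())

    @property
    def mean_precision(self) -> float:
        return float(self.precision_eukaryote.mean())

    @property
    def mean_recall(self) -> float:
        return float(self.recall_eukaryote.mean())

    @property
    def macro_precision(self) -> float:
        return float((self.precision_eukaryote + self.precision_prokaryote).mean() / 2)

    @property
    def macro_recall(self) -> float:
        return float((self.recall_eukaryote + self.recall_prokaryote).mean() / 2)

    def summary(self) -> str:
        lines = [
            f"{self.n_folds}-fold organism-grouped stratified cross-validation",
            "fold\taccuracy\tprecision(euk)\trecall(euk)",
        ]
        for i in range(self.n_folds):
            lines.append(
                f"{i}\t{self.accuracy[i]:.4f}\t"
                f"{self.precision_eukaryote[i]:.4f}\t{self.recall_eukaryote[i]:.4f}"
            )
        lines.append(
            f"mean\t{self.mean_accuracy:.4f} (sd {self.accuracy.std():.4f})\t"
            f"{self.mean_precision:.4f}\t{self.mean_recall:.4f}"
        )
        lines.append(
            f"macro-average precision {self.macro_precision:.4f}, "
            f"recall {self.macro_recall:.4f}"
        )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": np.arange(self.n_folds),
                "accuracy": self.accuracy,
                "precision_eukaryote": self.precision_eukaryote,
                "recall_eukaryote": self.recall_eukaryote,
                "precision_prokaryote": self.precision_prokaryote,
                "recall_prokaryote": self.recall_prokaryote,
            }
        )


def cross_validate_grouped(
    features: pd.DataFrame,
    labels: Sequence[str],
    groups: Sequence[str],
    n_folds: int = 5,
    seed: int = 0,
    n_estimators: int = 100,
) -> CVReport:
    """Organism-grouped stratified k-fold CV of the balanced forest.

    Each organism's contigs land in exactly one fold; folds approximate
    the global class proportions.  Raises :class:`ParameterError` when a
    class has fewer distinct organisms than folds.
    """
    X = _check_matrix(features)
    y = np.asarray(labels, dtype=object)
    g = np.asarray(groups, dtype=object)
    if not (len(X) == len(y) == len(g)):
        raise ParameterError("features, labels and groups disagree in length")
    for label in np.unique(y):
        n_groups = len(np.unique(g[y == label]))
        if n_groups < n_folds:
            raise ParameterError(
                f"class {label!r} has only {n_groups} organism group(s); "
                f"use n_folds <= {n_groups}"
            )

    splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    acc, p_euk, r_euk, p_prok, r_prok = [], [], [], [], []
    fold_assignments: dict[str, int] = {}
    fold_props: list[float] = []
    integrity = True
    for fold, (tr, te) in enumerate(splitter.split(X, y, g)):
        overlap = set(g[tr]) & set(g[te])
        if overlap:  # hard leakage guard, asserted on every run
            integrity = False
            raise AssertionError(
                f"organism groups leak across fold {fold}: {sorted(overlap)}"
            )
        est = ContigRandomForest(
            n_estimators=n_estimators, random_state=seed
        ).fit(X.iloc[tr], y[tr])
        pred = est.predict(X.iloc[te])
        truth = y[te]
        acc.append(accuracy_score(truth, pred))
        p_euk.append(precision_score(truth, pred, pos_label=EUKARYOTE, zero_division=0))
        r_euk.append(recall_score(truth, pred, pos_label=EUKARYOTE, zero_division=0))
        p_prok.append(precision_score(truth, pred, pos_label=PROKARYOTE, zero_division=0))
        r_prok.append(recall_score(truth, pred, pos_label=PROKARYOTE, zero_division=0))
        fold_props.append(float(np.mean(truth == EUKARYOTE)))
        for idx in te:
            fold_assignments[str(X.index[idx])] = fold

    return CVReport(
        n_folds=n_folds,
        accuracy=np.asarray(acc),
        precision_eukaryote=np.asarray(p_euk),
        recall_eukaryote=np.asarray(r_euk),
        precision_prokaryote=np.asarray(p_prok),
        recall_prokaryote=np.asarray(r_prok),
        fold_assignments=fold_assignments,
        group_integrity=integrity,
        fold_class_proportions=fold_props,
        global_class_proportion=float(np.mean(y == EUKARYOTE)),
    )


def save_model(model: TrainedModel, path: Union[str, Path]) -> None:
    """Persist a trained model (joblib) with an embedded schema version."""
    payload = {
        "schema_version": model.schema_version,
        "model": model,
    }
    joblib.dump(payload, path)


def load_model(path: Union[str, Path]) -> TrainedModel:
    """Load a model, refusing corrupt files or version mismatches."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # joblib/pickle raise a zoo of error types
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise ModelFormatError(f"{path} is not a karyon model file")
    version = payload["schema_version"]
    if version != MODEL_SCHEMA_VERSION:
        raise ModelVersionError(
            f"model schema {version!r} != expected {MODEL_SCHEMA_VERSION!r}; refusing to load"
        )
    return payload["model"]
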