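"""Supervised modelling harness: PCM regression and target feature-based
nested-CV classification.

PCM (proteochemometric) models concatenate a protein feature vector with a
compound fingerprint per bioactivity record and regress pChEMBL with a
random forest (100 trees, a third of the features per split).  The
small-scale, protein-only classification harness runs nested cross
validation (10-fold inner model selection, 5-fold outer testing) over the
standard RF/SVM grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import make_scorer, matthews_corrcoef
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from dtibench.errors import DimensionError, InputError
from dtibench.io import BioactivityTable, FeatureTable
from dtibench.metrics import classification_metrics, confusion_counts

RF_CLASSIFIER_GRID: Dict[str, list] = {"n_estimators": [200], "max_features": ["sqrt"]}
SVM_GRID: Dict[str, list] = {
    "svc__C": [1, 10, 100],
    "svc__gamma": [0.001, 0.01, 0.1, 1],
}


@dataclass
class ModelSpec:
    task: str = "regression"  # regression | classification
    algorithm: str = "random_forest"  # random_forest | svm_rbf
    hyperparameters: Dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("regression", "classification"):
            raise InputError(f"unknown task {self.task!r}")
        if self.algorithm not in ("random_forest", "svm_rbf"):
            raise InputError(f"unknown algorithm {self.algorithm!r}")


@dataclass
class PairFeatureMatrix:
    """Row-aligned design matrix for (compound, protein) records."""

    record_ids: List[int]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape[0] != len(self.record_ids) or self.y.shape[0] != len(self.record_ids):
            raise InputError("row count must equal the number of record ids")


def assemble_pcm_matrix(
    table: BioactivityTable,
    protein_features: Optional[FeatureTable],
    compound_features: Optional[FeatureTable],
    mode: str = "pcm",
    record_ids: Optional[Sequence[int]] = None,
) -> PairFeatureMatrix:
    """Build the design matrix for the requested records.

    mode 'pcm' concatenates protein ++ compound vectors; 'protein_only' and
    'compound_only' use a single side (the latter covers the only-ecfp4 /
    only-random-ecfp4 baselines).
    """
    if mode not in ("pcm", "protein_only", "compound_only"):
        raise InputError(f"unknown mode {mode!r}")
    ids = sorted(record_ids) if record_ids is not None else list(range(len(table)))
    need_protein = mode in ("pcm", "protein_only")
    need_compound = mode in ("pcm", "compound_only")
    missing: List[str] = []
    if need_protein:
        if protein_features is None:
            raise InputError("protein features required for this mode")
        missing += [
            f"protein:{table[i].protein_id}"
            for i in ids
            if table[i].protein_id not in protein_features
        ]
    if need_compound:
        if compound_features is None:
            raise InputError("compound features required for this mode")
        missing += [
            f"compound:{table[i].compound_id}"
            for i in ids
            if table[i].compound_id not in compound_features
        ]
    if missing:
        raise InputError(
            f"feature tables do not cover all records; missing: {sorted(set(missing))[:10]}"
        )
    rows = []
    for i in ids:
        rec = table[i]
        parts = []
        if need_protein:
            parts.append(protein_features[rec.protein_id])
        if need_compound:
            parts.append(compound_features[rec.compound_id])
        rows.append(np.concatenate(parts))
    X = np.stack(rows) if rows else np.empty((0, 0))
    y = np.array([table[i].activity for i in ids], dtype=float)
    return PairFeatureMatrix(ids, X, y)


def train_rf_regressor(matrix: PairFeatureMatrix, spec: Optional[ModelSpec] = None):
    """Random-forest pChEMBL regressor: 100 trees, max_features=0.33, seeded."""
    if spec is None:
        spec = ModelSpec(task="regression")
    if spec.task != "regression":
        raise InputError("train_rf_regressor requires a regression spec")
    if matrix.X.shape[0] < 5:
        raise InputError("need at least 5 training rows")
    params = {"n_estimators": 100, "max_features": 0.33, **spec.hyperparameters}
    model = RandomForestRegressor(random_state=spec.seed, n_jobs=1, **params)
    model.fit(matrix.X, matrix.y)
    model.n_features_expected_ = matrix.X.shape[1]
    return model


def predict(model, matrix: PairFeatureMatrix) -> np.ndarray:
    """Predictions aligned with matrix.record_ids."""
    expected = getattr(model, "n_features_expected_", getattr(model, "n_features_in_", None))
    if expected is not None and matrix.X.shape[1] != expected:
        raise DimensionError(
            f"matrix has {matrix.X.shape[1]} columns, model expects {expected}"
        )
    return np.asarray(model.predict(matrix.X), dtype=float)


def _make_estimator(spec: ModelSpec):
    if spec.algorithm == "random_forest":
        est = RandomForestClassifier(random_state=spec.seed, n_jobs=1)
        grid = RF_CLASSIFIER_GRID
    else:
        # rbf SVM needs comparable feature scales; scaler is fit per training fold
        est = Pipeline([("scaler", StandardScaler()), ("svc", SVC(kernel="rbf"))])
        grid = SVM_GRID
    return est, grid


def nested_cv_classify(
    matrix: PairFeatureMatrix,
    spec: Optional[ModelSpec] = None,
    inner_folds: int = 10,
    outer_folds: int = 5,
    grid: Optional[Mapping[str, list]] = None,
) -> Dict:
    """Nested cross-validated binary classification.

    Stratified outer folds; the inner loop grid-searches hyperparameters by
    mean MCC; outer folds are scored untouched.  Returns per-fold metric
    dicts plus their unweighted mean.
    """
    if spec is None:
        spec = ModelSpec(task="classification")
    if spec.task != "classification":
        raise InputError("nested_cv_classify requires a classification spec")
    y = matrix.y.astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise InputError(f"binary labels required, got classes {classes.tolist()}")
    if counts.min() < outer_folds:
        raise InputError(
            f"need >= {outer_folds} samples per class for stratified outer folds"
        )
    estimator, default_grid = _make_estimator(spec)
    grid = dict(grid) if grid is not None else default_grid
    mcc_scorer = make_scorer(matthews_corrcoef)
    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=spec.seed)
    fold_reports: List[Dict[str, float]] = []
    chosen_params: List[Dict] = []
    for train_idx, test_idx in outer.split(matrix.X, y):
        inner = StratifiedKFold(
            n_splits=min(inner_folds, np.bincount(y[train_idx]).min()),
            shuffle=True,
            random_state=spec.seed,
        )
        search = GridSearchCV(estimator, grid, scoring=mcc_scorer, cv=inner, n_jobs=1)
        search.fit(matrix.X[train_idx], y[train_idx])
        y_hat = search.predict(matrix.X[test_idx])
        fold_reports.append(
            classification_metrics(confusion_counts(y[test_idx], y_hat))
        )
        chosen_params.append(search.best_params_)
    aggregate = {
        key: float(np.mean([r[key] for r in fold_reports]))
        for key in fold_reports[0]
    }
    return {"folds": fold_reports, "aggregate": aggregate, "best_params": chosen_params}
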