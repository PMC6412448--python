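"""Tree-ensemble regression from waveform features to SBP/DBP.

Three algorithms are supported, each fitted separately per target
(SBP or DBP): random forest regression (RFR), gradient boosting
regression (GBR) and AdaBoost regression (ABR).  They are standard
scikit-learn estimators; this module owns the split protocol, the
feature schema, determinism and persistence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.tree import DecisionTreeRegressor

from pulsebp.features import FEATURE_NAMES

__all__ = [
    "ALGORITHMS",
    "TARGETS",
    "ModelSpec",
    "FittedModel",
    "split_dataset",
    "train_model",
    "predict",
    "save_model",
    "load_model",
]

ALGORITHMS = ("RFR", "GBR", "ABR")
TARGETS = ("SBP", "DBP")
TARGET_COLUMNS = {"SBP": "sbp_mmHg", "DBP": "dbp_mmHg"}


@dataclass
class ModelSpec:
    """Algorithm, target and hyperparameters for one regressor.

    Defaults: 100 estimators for every algorithm; unconstrained tree
    depth for the forest, depth-3 base learners for both boosting
    methods, learning rate 0.1 for gradient boosting.
    """

    algorithm: str
    target: str
    n_estimators: int = 100
    max_depth: int | None = None   # RFR trees; boosting uses base_depth
    base_depth: int = 3
    learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")

    def build_estimator(self):
        if self.algorithm == "RFR":
            return RandomForestRegressor(
                n_estimators=self.n_estimators, max_depth=self.max_depth,
                random_state=self.seed, n_jobs=1)
        if self.algorithm == "GBR":
            return GradientBoostingRegressor(
                n_estimators=self.n_estimators, max_depth=self.base_depth,
                learning_rate=self.learning_rate, random_state=self.seed)
        return AdaBoostRegressor(
            estimator=DecisionTreeRegressor(max_depth=self.base_depth),
            n_estimators=self.n_estimators, random_state=self.seed)


@dataclass
class FittedModel:
    """A trained regressor plus the schema it was trained on."""

    estimator: object
    spec: ModelSpec
    feature_names: tuple[str, ...]


def split_dataset(
    dataset: pd.DataFrame,
    ratio: float = 0.8,
    seed: int = 0,
    mode: str = "record",
) -> pd.DataFrame:
    """Assign a train/test split label to every record.

    ``record`` mode draws a uniform random partition of records with
    ``round(ratio * n)`` training rows (Python banker's rounding, i.e.
    round-half-even).  ``subject`` mode keeps all records of a subject
    on the same side, adding whole subjects in random order until the
    training side reaches the target count (so the achieved fraction is
    approximate).  Deterministic for a fixed seed; raises if either
    side would be empty.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    if mode not in ("record", "subject"):
        raise ValueError("mode must be 'record' or 'subject'")
    n = len(dataset)
    n_train = int(round(ratio * n))
    if n_train == 0 or n_train == n:
        raise ValueError("split would leave one side empty")
    rng = np.random.default_rng(seed)
    out = dataset.copy()
    if mode == "record":
        perm = rng.permutation(n)
        labels = np.full(n, "test", dtype=object)
        labels[perm[:n_train]] = "train"
    else:
        subjects = dataset["subject_id"].to_numpy()
        uniq = pd.unique(subjects)
        order = rng.permutation(len(uniq))
        train_subjects: set[str] = set()
        count = 0
        for i in order:
            if count >= n_train:
                break
            if len(train_subjects) == len(uniq) - 1:
                break  # always leave at least one subject for testing
            train_subjects.add(uniq[i])
            count += int(np.sum(subjects == uniq[i]))
        labels = np.where(
            np.isin(subjects, list(train_subjects)), "train", "test")
        if (labels == "test").sum() == 0 or (labels == "train").sum() == 0:
            raise ValueError("subject-mode split left one side empty")
    out["split"] = labels
    return out


def _feature_matrix(df: pd.DataFrame,
                    feature_names: tuple[str, ...]) -> np.ndarray:
    for col in feature_names:
        if col not in df.columns:
            raise KeyError(f"feature column {col!r} missing from input")
    X = df.loc[:, list(feature_names)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    return X


def train_model(
    spec: ModelSpec,
    train_df: pd.DataFrame,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> FittedModel:
    """Fit one regressor on the training partition.

    Raises on an empty partition or when every feature column has zero
    variance (nothing to learn from).
    """
    if len(train_df) == 0:
        raise ValueError("training partition is empty")
    X = _feature_matrix(train_df, feature_names)
    if len(train_df) > 1 and float(np.ptp(X, axis=0).max()) == 0.0:
        raise ValueError("all feature columns have zero variance")
    y = train_df[TARGET_COLUMNS[spec.target]].to_numpy(dtype=float)
    est = spec.build_estimator()
    est.fit(X, y)
    return FittedModel(estimator=est, spec=spec,
                       feature_names=tuple(feature_names))


def predict(model: FittedModel, df: pd.DataFrame) -> np.ndarray:
    """Predict BP (mmHg) for each row; validates the feature schema."""
    X = _feature_matrix(df, model.feature_names)
    yhat = np.asarray(model.estimator.predict(X), dtype=float)
    if not np.all(np.isfinite(yhat)):
        raise ValueError("model produced non-finite predictions")
    return yhat


def save_model(model: FittedModel, path: str | Path) -> None:
    """Persist estimator + spec + schema in one artifact file."""
    joblib.dump({
        "estimator": model.estimator,
        "spec": asdict(model.spec),
        "feature_names": list(model.feature_names),
    }, path)


def load_model(path: str | Path) -> FittedModel:
    blob = joblib.load(path)
    return FittedModel(
        estimator=blob["estimator"],
        spec=ModelSpec(**blob["spec"]),
        feature_names=tuple(blob["feature_names"]),
    )
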