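"""Training and evaluation of the three behavior classifiers.

The labeled feature table is split 70/30 into training and validation
(stratified by behavior by default; a grouped-by-animal strategy is
available because per-animal leakage is the realistic concern).  Three
model families are supported:

* ``forest`` — random forest, 500 trees, other structural controls at the
  library defaults;
* ``convnet`` — a dense feed-forward network on the per-record feature
  vector with three layers of 24/12/6 units (relu/relu/softmax), adam
  optimizer, batch size 128, up to 500 epochs with a 0.2 validation split
  monitored for early stopping, behind a standardizing scaler;
* ``lda`` — linear discriminant analysis with no tunables.

Model inputs are the eight derived signal variables plus hour/minute/second
and reference-coded genetic-group indicators; sensor identity is excluded
by default to avoid identity leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .behaviors import GENETIC_GROUPS
from .features import FEATURE_COLUMNS
from .metrics import EvalSummary, confusion_matrix, overall_metrics

DEFAULT_MODEL_COLUMNS = FEATURE_COLUMNS + ["hour", "minute", "second"]


@dataclass(frozen=True)
class SplitSpec:
    """70/30 train-validation split specification."""

    train_fraction: float = 0.70
    strategy: str = "stratified_by_label"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.strategy not in {"random", "stratified_by_label", "grouped_by_animal"}:
            raise ValueError(f"unknown split strategy {self.strategy!r}")


@dataclass(frozen=True)
class ClassifierConfig:
    """Configuration of one model family."""

    kind: str = "forest"
    n_trees: int = 500
    layer_widths: tuple[int, ...] = (24, 12)  # hidden; output layer = 6 softmax
    epochs: int = 500
    validation_split: float = 0.2
    batch_size: int = 128
    seed: int = 0
    n_jobs: int = 1
    use_genetic_group: bool = True
    feature_columns: tuple[str, ...] = tuple(DEFAULT_MODEL_COLUMNS)

    def __post_init__(self) -> None:
        if self.kind not in {"forest", "convnet", "lda"}:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if any(w < 1 for w in self.layer_widths) or self.epochs < 1:
            raise ValueError("layer widths and epochs must be positive")


@dataclass
class BehaviorClassifier:
    """A fitted model plus the bookkeeping needed to predict reproducibly."""

    model: object
    classes: tuple[str, ...]
    feature_columns: tuple[str, ...]
    config: ClassifierConfig


def split_dataset(
    table: pd.DataFrame, spec: SplitSpec = SplitSpec()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/validation split, reproducible by seed."""
    if table.empty:
        raise ValueError("cannot split an empty table")
    if spec.strategy == "stratified_by_label" and "behavior" not in table.columns:
        raise ValueError("stratified split needs a behavior column")
    n_train = int(round(spec.train_fraction * len(table)))
    n_train = min(max(n_train, 1), len(table) - 1)
    if spec.strategy == "grouped_by_animal":
        rng = np.random.default_rng(spec.seed)
        animals = table["animal_id"].unique()
        rng.shuffle(animals)
        counts = table["animal_id"].value_counts()
        cum, chosen = 0, []
        for a in animals:
            if cum >= n_train:
                break
            chosen.append(a)
            cum += counts[a]
        mask = table["animal_id"].isin(chosen)
        return table[mask], table[~mask]
    stratify = None
    if spec.strategy == "stratified_by_label":
        counts = table["behavior"].value_counts()
        thin = counts[counts < 2]
        if not thin.empty:
            raise ValueError(
                f"stratified split needs >= 2 rows per class; too few for "
                f"{', '.join(thin.index.astype(str))}"
            )
        stratify = table["behavior"]
    train, validation = train_test_split(
        table,
        train_size=n_train,
        random_state=spec.seed,
        shuffle=True,
        stratify=stratify,
    )
    return train, validation


def _design_matrix(
    table: pd.DataFrame, config: ClassifierConfig
) -> pd.DataFrame:
    missing = [c for c in config.feature_columns if c not in table.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {', '.join(missing)}")
    X = table[list(config.feature_columns)].astype(float)
    if config.use_genetic_group:
        if "genetic_group" not in table.columns:
            raise ValueError("missing feature column(s): genetic_group")
        for group in GENETIC_GROUPS[1:]:  # reference-coded indicators
            X[f"group_{group}"] = (table["genetic_group"] == group).astype(float)
    return X


def _make_estimator(config: ClassifierConfig):
    if config.kind == "forest":
        return RandomForestClassifier(
            n_estimators=config.n_trees,
            random_state=config.seed,
            n_jobs=config.n_jobs,
        )
    if config.kind == "convnet":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "net",
                    MLPClassifier(
                        hidden_layer_sizes=tuple(config.layer_widths),
                        activation="relu",
                        solver="adam",
                        batch_size=config.batch_size,
                        max_iter=config.epochs,
                        early_stopping=True,
                        validation_fraction=config.validation_split,
                        random_state=config.seed,
                    ),
                ),
            ]
        )
    return LinearDiscriminantAnalysis()


def train_classifier(
    train: pd.DataFrame, config: ClassifierConfig = ClassifierConfig()
) -> BehaviorClassifier:
    """Fit one model family on a labeled feature table."""
    classes = tuple(sorted(train["behavior"].unique()))
    if len(classes) < 2:
        raise ValueError("training set must contain at least two classes")
    X = _design_matrix(train, config)
    estimator = _make_estimator(config)
    estimator.fit(X.to_numpy(), train["behavior"].to_numpy(dtype=object))
    return BehaviorClassifier(
        model=estimator,
        classes=classes,
        feature_columns=tuple(X.columns),
        config=config,
    )


def predict(classifier: BehaviorClassifier, table: pd.DataFrame) -> np.ndarray:
    """One behavior label per row; deterministic given a fitted model."""
    if table.empty:
        return np.array([], dtype=object)
    X = _design_matrix(table, classifier.config)
    if tuple(X.columns) != classifier.feature_columns:
        raise ValueError("feature columns differ from those seen at training")
    return classifier.model.predict(X.to_numpy()).astype(object)


def evaluate_classifier(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    config: ClassifierConfig,
) -> tuple[EvalSummary, np.ndarray]:
    """Train on *train*, score on *validation*; returns (summary, predictions)."""
    clf = train_classifier(train, config)
    pred = predict(clf, validation)
    cm = confusion_matrix(validation["behavior"].to_numpy(dtype=object), pred)
    return overall_metrics(cm), pred


def evaluate_transfer(
    table: pd.DataFrame,
    train_filter: pd.Series,
    test_filter: pd.Series,
    config: ClassifierConfig = ClassifierConfig(),
) -> EvalSummary:
    """Train on one subset (e.g. one season) and evaluate on a disjoint one."""
    train_filter = train_filter.astype(bool)
    test_filter = test_filter.astype(bool)
    if (train_filter & test_filter).any():
        raise ValueError("train and test subsets overlap")
    train = table[train_filter]
    test = table[test_filter]
    if train.empty or test.empty:
        raise ValueError("both subsets must be non-empty")
    summary, _ = evaluate_classifier(train, test, config)
    return summary
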