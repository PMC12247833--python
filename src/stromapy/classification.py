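"""Cell classification by translated thresholds or a random forest, and
agreement statistics between labelings.

Two routes produce marker-positive/negative (and cancer/non-cancer) labels:

- threshold route: a cell is positive iff its marker measurement is
  *strictly* greater than its image's translated threshold;
- supervised route: a random forest trained on intensity features of a
  manually labelled subset.

Agreement between any two labelings is summarised by a confusion matrix and
the percentage of cells on its diagonal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .calibration import ThresholdMap

__all__ = [
    "ConfusionSummary",
    "classify_by_threshold",
    "RandomForestCellClassifier",
    "train_rf",
    "agreement",
]


@dataclass
class ConfusionSummary:
    """Confusion matrix between two labelings of the same cells."""

    labels: list
    matrix: np.ndarray   # rows = method A, cols = method B
    agreement_pct: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def classify_by_threshold(
    table: pd.DataFrame, threshold_map: ThresholdMap, label_column: str | None = None
) -> pd.DataFrame:
    """Append a boolean positivity column using per-image translated thresholds.

    Positivity is strict: a value exactly equal to the threshold is negative.
    The label column defaults to ``class_<marker>`` and the call can be
    composed for a second marker (e.g. a cytokeratin gate for cancer cells).
    """
    if threshold_map.marker not in table.columns:
        raise KeyError(f"marker column {threshold_map.marker!r} missing from table")
    out = table.copy()
    label_column = label_column or f"class_{threshold_map.marker}"
    thresholds = out["image_id"].map(
        lambda img: threshold_map.threshold_for(str(img))
    )
    out[label_column] = out[threshold_map.marker].to_numpy() > thresholds.to_numpy()
    return out


@dataclass
class RandomForestCellClassifier:
    """A fitted random forest over intensity feature columns."""

    model: RandomForestClassifier
    feature_columns: list[str]
    classes: list

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_columns if c not in table.columns]
        if missing:
            raise KeyError(f"feature columns missing from table: {missing}")
        return self.model.predict(table[self.feature_columns].to_numpy())

    def describe(self) -> dict:
        """JSON-serialisable description of the model (schema v1)."""
        return {
            "schema_version": 1,
            "kind": "random_forest",
            "feature_columns": self.feature_columns,
            "classes": [str(c) for c in self.classes],
            "n_estimators": self.model.n_estimators,
            "random_state": self.model.random_state,
        }

    def save_description(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.describe(), indent=2))


def train_rf(
    training: pd.DataFrame,
    feature_columns: Sequence[str],
    label_column: str,
    seed: int = 0,
    n_estimators: int = 100,
) -> RandomForestCellClassifier:
    """Train a random forest on intensity features of an annotated subset.

    Requires at least two classes with >= 5 examples each; deterministic for
    a given seed.
    """
    feature_columns = list(feature_columns)
    missing = [c for c in feature_columns + [label_column] if c not in training.columns]
    if missing:
        raise KeyError(f"columns missing from training table: {missing}")
    y = training[label_column].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 classes")
    if counts.min() < 5:
        raise ValueError(
            f"every class needs >= 5 training examples (got {dict(zip(classes, counts))})"
        )
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    model.fit(training[feature_columns].to_numpy(), y)
    return RandomForestCellClassifier(
        model=model, feature_columns=feature_columns, classes=list(classes)
    )


def agreement(labels_a: Sequence, labels_b: Sequence) -> ConfusionSummary:
    """Confusion matrix (rows = A, cols = B) and percent agreement."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("cannot compute agreement on empty labelings")
    labels = sorted(set(a.tolist()) | set(b.tolist()), key=str)
    index = {lab: i for i, lab in enumerate(labels)}
    matrix = np.zeros((len(labels), len(labels)), dtype=int)
    for x, y in zip(a, b):
        matrix[index[x], index[y]] += 1
    agreement_pct = 100.0 * np.trace(matrix) / len(a)
    return ConfusionSummary(labels=labels, matrix=matrix, agreement_pct=agreement_pct)
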