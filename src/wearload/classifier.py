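"""Training, evaluation, pruning and export of the activity classifier.

The working model is a random forest over the windowed accelerometer
features (24 trees on the 11-feature set by default); k-nearest neighbours
(5 neighbours) is kept as the comparison baseline.  Feature relevance is
measured with normalized Gini importance (mean impurity decrease), which
drives the pruning of the full 15-feature set down to 11.

A fitted forest can be exported to a language-neutral JSON description —
every split node and leaf vote of every tree — and replayed by a small
bundled interpreter whose predictions match the live model exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

from .features import LABEL_COLUMN, FeatureSetSpec

__all__ = [
    "DEFAULT_TREES",
    "DEFAULT_NEIGHBORS",
    "TrainedModel",
    "EvaluationReport",
    "split_dataset",
    "train_model",
    "evaluate_model",
    "sweep_size",
    "rank_importance",
    "select_pruned_spec",
    "export_model",
    "ForestDescription",
    "load_model_description",
]

#: Final model defaults: 24 trees after the stability sweep; 5-NN baseline.
DEFAULT_TREES = 24
DEFAULT_NEIGHBORS = 5

_MAX_SIZE_PARAM = 1000


def _child_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage sub-seed derived from the global seed."""
    return int((seed * 1_000_003 + stage) % 2_147_483_647)


@dataclass
class TrainedModel:
    """A fitted classifier plus the metadata needed to reuse it."""

    algorithm: str  # "random_forest" | "knn"
    size_param: int  # tree count or neighbour count
    feature_spec: FeatureSetSpec
    class_list: tuple[str, ...]
    estimator: object
    seed: int

    def _matrix(self, vectors: pd.DataFrame) -> np.ndarray:
        missing = [n for n in self.feature_spec.names if n not in vectors.columns]
        if missing:
            raise ValueError(f"feature matrix is missing columns {missing}")
        return vectors.loc[:, list(self.feature_spec.names)].to_numpy(dtype=float)

    def predict(self, vectors: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(self._matrix(vectors))


@dataclass
class EvaluationReport:
    """Confusion matrix (per-true-class normalized) and accuracies."""

    confusion: pd.DataFrame  # rows: true class, cols: predicted; rows sum to 1
    counts: pd.DataFrame  # raw tallies
    overall_accuracy: float
    per_class_accuracy: dict[str, float]
    support: dict[str, int]
    zero_support_classes: tuple[str, ...]


def split_dataset(
    vectors: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified, seeded train/validation split (default 70/30).

    The two frames are disjoint and exhaustive; shuffling is driven entirely
    by ``seed``.  Every class must contribute at least two vectors so both
    halves see every class.
    """
    if LABEL_COLUMN not in vectors.columns:
        raise ValueError("vectors must carry a label column")
    counts = vectors[LABEL_COLUMN].value_counts()
    thin = counts[counts < 2]
    if not thin.empty:
        raise ValueError(
            f"class(es) with fewer than 2 vectors cannot be split: {sorted(thin.index)}"
        )
    train, valid = train_test_split(
        vectors,
        train_size=train_fraction,
        random_state=seed,
        shuffle=True,
        stratify=vectors[LABEL_COLUMN],
    )
    return train, valid


def train_model(
    train_set: pd.DataFrame,
    algorithm: str = "random_forest",
    size_param: int = DEFAULT_TREES,
    seed: int = 0,
    feature_spec: Optional[FeatureSetSpec] = None,
) -> TrainedModel:
    """Fit a random forest (``size_param`` trees) or kNN (``size_param``
    neighbours) on a labeled feature matrix; deterministic given ``seed``."""
    if train_set.empty:
        raise ValueError("training set is empty")
    if not (1 <= size_param <= _MAX_SIZE_PARAM):
        raise ValueError(f"size_param={size_param} outside 1..{_MAX_SIZE_PARAM}")
    if feature_spec is None:
        feature_spec = FeatureSetSpec(
            tuple(c for c in train_set.columns if c != LABEL_COLUMN)
        )
    X = train_set.loc[:, list(feature_spec.names)].to_numpy(dtype=float)
    y = train_set[LABEL_COLUMN].to_numpy()

    if algorithm == "random_forest":
        est = RandomForestClassifier(n_estimators=size_param, random_state=seed)
    elif algorithm == "knn":
        n_neighbors = min(size_param, len(train_set))
        est = KNeighborsClassifier(n_neighbors=n_neighbors)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    est.fit(X, y)
    return TrainedModel(
        algorithm=algorithm,
        size_param=size_param,
        feature_spec=feature_spec,
        class_list=tuple(sorted(np.unique(y).tolist())),
        estimator=est,
        seed=seed,
    )


def evaluate_model(model, vectors: pd.DataFrame) -> EvaluationReport:
    """Exact-count confusion matrix and accuracies on a labeled set.

    ``model`` needs only ``predict`` and ``class_list``, so replayed model
    descriptions and test stubs evaluate through the same path as live
    models.  Rows of the normalized matrix sum to 1; classes with zero
    support keep an all-zero row and are flagged.
    """
    if vectors.empty:
        raise ValueError("evaluation set is empty")
    labels = vectors[LABEL_COLUMN].to_numpy()
    classes = tuple(model.class_list)
    unknown = sorted(set(labels) - set(classes))
    if unknown:
        raise ValueError(f"labels outside the model's class list: {unknown}")
    predicted = np.asarray(model.predict(vectors))

    counts = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for t, p in zip(labels, predicted):
        counts.loc[t, p] += 1
    support = counts.sum(axis=1)
    normalized = counts.div(support.replace(0, 1), axis=0).astype(float)
    correct = int(np.sum(predicted == labels))
    per_class = {
        c: (counts.loc[c, c] / support[c]) if support[c] else float("nan")
        for c in classes
    }
    return EvaluationReport(
        confusion=normalized,
        counts=counts,
        overall_accuracy=correct / len(labels),
        per_class_accuracy=per_class,
        support={c: int(support[c]) for c in classes},
        zero_support_classes=tuple(c for c in classes if support[c] == 0),
    )


def sweep_size(
    train_set: pd.DataFrame,
    valid_set: pd.DataFrame,
    algorithm: str,
    size_range: Sequence[int],
    seed: int = 0,
) -> list[tuple[int, float]]:
    """Accuracy curve over model sizes (tree or neighbour counts).

    One model is trained per size on the same split, each with a sub-seed
    derived from the global seed and the size, and scored on the validation
    set.
    """
    sizes = list(size_range)
    if not sizes:
        raise ValueError("size_range is empty")
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("size_range must be ascending")
    curve = []
    for size in sizes:
        model = train_model(
            train_set, algorithm=algorithm, size_param=size, seed=_child_seed(seed, size)
        )
        report = evaluate_model(model, valid_set)
        curve.append((size, report.overall_accuracy))
    return curve


def rank_importance(model: TrainedModel) -> dict[str, float]:
    """Normalized Gini (mean impurity decrease) importance per feature.

    Only defined for random forests; the returned dict is ordered by the
    model's canonical feature order and its values sum to 1.
    """
    if model.algorithm != "random_forest":
        raise ValueError("feature importance is only defined for random forests")
    raw = np.asarray(model.estimator.feature_importances_, dtype=float)
    total = raw.sum()
    norm = raw / total if total > 0 else np.full_like(raw, 1.0 / len(raw))
    return dict(zip(model.feature_spec.names, norm.tolist()))


def select_pruned_spec(ranking: dict[str, float], drop_count: int) -> FeatureSetSpec:
    """Feature set excluding the ``drop_count`` least-important features.

    Ties in importance break by the ranking's own (canonical) order, keeping
    the earlier-listed feature.
    """
    names = list(ranking.keys())
    if not (0 <= drop_count < len(names)):
        raise ValueError(
            f"drop_count={drop_count} must be in 0..{len(names) - 1}"
        )
    # stable sort: among equal importances the later-listed feature drops first
    order = sorted(range(len(names)), key=lambda i: (ranking[names[i]], -i))
    dropped = {names[i] for i in order[:drop_count]}
    return FeatureSetSpec(tuple(n for n in names if n not in dropped))


# --------------------------------------------------------------------------
# portable model description

@dataclass
class ForestDescription:
    """Language-neutral random-forest description and its interpreter.

    Each tree is a flat node list; node ``i`` holds a split feature index,
    threshold and child indices, or ``feature == -1`` with per-class leaf
    vote weights.  Prediction averages the normalized leaf votes across
    trees and takes the arg-max class, ties resolving to the first class in
    the (alphabetical) class list — the same rule the live model applies.
    """

    algorithm: str
    n_trees: int
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    trees: list[dict]

    @property
    def class_list(self) -> tuple[str, ...]:
        return self.classes

    @property
    def feature_spec(self) -> FeatureSetSpec:
        return FeatureSetSpec(self.feature_names)

    def _tree_proba(self, tree: dict, x: np.ndarray) -> np.ndarray:
        nodes = tree["nodes"]
        i = 0
        while True:
            node = nodes[i]
            if node["feature"] < 0:
                votes = np.asarray(node["votes"], dtype=float)
                return votes / votes.sum()
            i = node["left"] if x[node["feature"]] <= node["threshold"] else node["right"]

    def predict_proba(self, vectors: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(vectors, pd.DataFrame):
            X = vectors.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        else:
            X = np.asarray(vectors, dtype=float)
        proba = np.zeros((len(X), len(self.classes)))
        for r, x in enumerate(X):
            proba[r] = np.mean([self._tree_proba(t, x) for t in self.trees], axis=0)
        return proba

    def predict(self, vectors: pd.DataFrame | np.ndarray) -> np.ndarray:
        proba = self.predict_proba(vectors)
        idx = np.argmax(proba, axis=1)  # first max wins -> alphabetical tie-break
        return np.asarray(self.classes, dtype=object)[idx]

    def n_split_nodes(self) -> int:
        return sum(
            1 for t in self.trees for node in t["nodes"] if node["feature"] >= 0
        )


def export_model(model: TrainedModel, path: str | Path) -> None:
    """Write a fitted random forest as a JSON model description."""
    if model.algorithm != "random_forest":
        raise ValueError("only random forests can be exported")
    est = model.estimator
    if not hasattr(est, "estimators_"):
        raise ValueError("model is not fitted")
    trees = []
    for tree in est.estimators_:
        t = tree.tree_
        nodes = []
        for i in range(t.node_count):
            if t.children_left[i] == -1:  # leaf
                nodes.append(
                    {"feature": -1, "votes": t.value[i][0].tolist()}
                )
            else:
                nodes.append(
                    {
                        "feature": int(t.feature[i]),
                        "threshold": float(t.threshold[i]),
                        "left": int(t.children_left[i]),
                        "right": int(t.children_right[i]),
                    }
                )
        trees.append({"nodes": nodes})
    doc = {
        "algorithm": "random_forest",
        "n_trees": len(trees),
        "feature_names": list(model.feature_spec.names),
        "classes": [str(c) for c in est.classes_],
        "trees": trees,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_model_description(path: str | Path) -> ForestDescription:
    """Load a JSON model description written by :func:`export_model`."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    return ForestDescription(
        algorithm=doc["algorithm"],
        n_trees=int(doc["n_trees"]),
        feature_names=tuple(doc["feature_names"]),
        classes=tuple(doc["classes"]),
        trees=doc["trees"],
    )
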