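"""Weighted template-matching classifier and the LSVM / random-forest baselines.

Each class is summarized by a template: the elementwise mean of its
reweighted training vectors over the retained features. A test vector
(reweighted the same way) is assigned to the class whose template it
is most similar to — cosine similarity by default, falling back to
negative Euclidean distance when either vector is all-zero (cosine is
undefined there). Ties go to the earliest class in training-label
order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

from .ga import Chromosome


@dataclass
class ClassTemplate:
    class_label: str
    template: np.ndarray


@dataclass
class TrainedModel:
    """Serializable bundle: templates, GA weights, retained features,
    normalization extremes, and the config snapshot used to train."""

    templates: list[ClassTemplate]
    weights: Chromosome | None
    feature_names: list[str]
    extremes: list[tuple[float, float]] | None = None
    config: dict = field(default_factory=dict)
    similarity: str = "cosine"

    def to_json(self, path: str | Path) -> None:
        data = {
            "templates": {t.class_label: t.template.tolist() for t in self.templates},
            "weights": self.weights.weights.tolist() if self.weights else None,
            "feature_names": self.feature_names,
            "extremes": self.extremes,
            "config": self.config,
            "similarity": self.similarity,
        }
        Path(path).write_text(json.dumps(data, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        data = json.loads(Path(path).read_text())
        return cls(
            templates=[
                ClassTemplate(label, np.array(vec))
                for label, vec in data["templates"].items()
            ],
            weights=Chromosome(np.array(data["weights"])) if data["weights"] else None,
            feature_names=data["feature_names"],
            extremes=[tuple(e) for e in data["extremes"]] if data["extremes"] else None,
            config=data.get("config", {}),
            similarity=data.get("similarity", "cosine"),
        )


def build_templates(
    train_table: np.ndarray, labels: np.ndarray, class_order: list[str] | None = None
) -> list[ClassTemplate]:
    """Per-class elementwise means of the (already reweighted, retained)
    training vectors."""
    X = np.asarray(train_table, dtype=float)
    y = np.asarray(labels)
    order = class_order if class_order is not None else list(dict.fromkeys(y))
    templates = []
    for label in order:
        mask = y == label
        if not mask.any():
            raise ValueError(f"class {label!r} has no training samples")
        templates.append(ClassTemplate(str(label), X[mask].mean(axis=0)))
    return templates


def _similarity(v: np.ndarray, t: np.ndarray, metric: str) -> float:
    if metric == "euclidean":
        return -float(np.linalg.norm(v - t))
    nv, nt = np.linalg.norm(v), np.linalg.norm(t)
    if nv == 0.0 or nt == 0.0:
        return -float(np.linalg.norm(v - t))
    return float(np.dot(v, t) / (nv * nt))


def match(
    test_vector: np.ndarray, model: TrainedModel
) -> tuple[str, dict[str, float]]:
    """Predicted label and per-class similarity scores for one vector."""
    v = np.asarray(test_vector, dtype=float)
    scores: dict[str, float] = {}
    best_label, best_score = None, -np.inf
    for tmpl in model.templates:
        if len(tmpl.template) != len(v):
            raise ValueError(
                f"test vector has {len(v)} features but template "
                f"{tmpl.class_label!r} has {len(tmpl.template)}"
            )
        s = _similarity(v, tmpl.template, model.similarity)
        scores[tmpl.class_label] = s
        if s > best_score:  # strict: ties keep the earlier class
            best_label, best_score = tmpl.class_label, s
    assert best_label is not None
    return best_label, scores


class TemplateMatchingClassifier(BaseEstimator, ClassifierMixin):
    """Nearest weighted-template classifier, sklearn-style.

    ``fit`` stores one template per class (the class mean of the
    training vectors, which are expected to be already reweighted by
    the GA selector when used in the full pipeline); ``predict``
    assigns each row to the most similar template.

    Parameters
    ----------
    metric : {"cosine", "euclidean"}
        Similarity used for matching.
    """

    def __init__(self, metric: str = "cosine"):
        self.metric = metric

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        self.classes_ = np.array(list(dict.fromkeys(y)))
        self.templates_ = np.vstack(
            [X[y == c].mean(axis=0) for c in self.classes_]
        )
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "templates_")
        X = np.asarray(X, dtype=float)
        scores = np.empty((len(X), len(self.classes_)))
        for i, row in enumerate(X):
            for j, tmpl in enumerate(self.templates_):
                scores[i, j] = _similarity(row, tmpl, self.metric)
        return scores

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def to_model(
        self,
        feature_names: list[str],
        weights: Chromosome | None = None,
        extremes=None,
        config: dict | None = None,
    ) -> TrainedModel:
        check_is_fitted(self, "templates_")
        return TrainedModel(
            templates=[
                ClassTemplate(str(c), t.copy())
                for c, t in zip(self.classes_, self.templates_)
            ],
            weights=weights,
            feature_names=feature_names,
            extremes=extremes,
            config=config or {},
            similarity=self.metric,
        )


def train_baseline(kind: str, train_table: np.ndarray, labels: np.ndarray, seed: int = 0):
    """The two comparison classifiers: 'lsvm' (linear kernel, C=1) and
    'rf' (100 trees) — the same configurations used inside the GA
    fitness function."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("baseline training needs at least 2 classes")
    if kind == "lsvm":
        clf = LinearSVC(C=1.0, dual="auto", max_iter=5000, random_state=seed % (2**31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(train_table, y)
        return clf
    if kind == "rf":
        clf = RandomForestClassifier(
            n_estimators=100, random_state=seed % (2**31), n_jobs=1
        )
        return clf.fit(train_table, y)
    raise ValueError(f"unknown baseline kind {kind!r}; use 'lsvm' or 'rf'")


def predict_baseline(model, table: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(table, dtype=float))
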