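"""Drug-target pair classification with gradient-boosted trees.

A candidate pair (drug i, target j) is represented by the concatenation
h = [X_i, X_j] of the two smoothed node embeddings (drug block first). A
gradient-boosted decision tree ensemble scores each pair with an
interaction probability in [0, 1]; pairs above the cutoff (strictly) are
called interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GbdtConfig",
    "PairDataset",
    "GBDTPairClassifier",
    "make_pair_features",
    "train_classifier",
    "score_pairs",
    "call_interactions",
    "rank_candidates",
    "save_model",
    "load_model",
]


@dataclass
class GbdtConfig:
    """Ensemble hyperparameters: T regression trees, shrinkage, tree depth."""

    n_trees: int = 500
    learning_rate: float = 0.1
    max_depth: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("need at least one tree")


@dataclass(frozen=True)
class PairDataset:
    """Labelled drug-target pairs with concatenated embedding features."""

    pairs: tuple[tuple[int, int], ...]
    labels: np.ndarray = field(repr=False)
    features: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate (drug, target) pair in dataset")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")


def make_pair_features(
    X: np.ndarray, pairs: list[tuple[int, int]], n_drugs: int
) -> np.ndarray:
    """h = [X_drug, X_target] for each (drug_index, target_index) pair.

    Indices are global: a valid pair has drug index < n_drugs <= target
    index. Anything else (two drugs, two targets, swapped order) is
    rejected.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    out = np.empty((len(pairs), 2 * X.shape[1]), dtype=np.float64)
    d = X.shape[1]
    for row, (i, j) in enumerate(pairs):
        if not (0 <= i < n_drugs):
            raise ValueError(f"pair ({i}, {j}): first index is not a drug")
        if not (n_drugs <= j < n):
            raise ValueError(f"pair ({i}, {j}): second index is not a target")
        out[row, :d] = X[i]
        out[row, d:] = X[j]
    return out


class GBDTPairClassifier(BaseEstimator, ClassifierMixin):
    """Gradient-boosted decision tree classifier over pair features.

    Thin sklearn-idiomatic wrapper fixing the binary-DTI conventions:
    probability scores via ``score_pairs``, strict-cutoff calls, and a
    deterministic seed. Composes with sklearn pipelines and CV utilities.
    """

    def __init__(
        self,
        n_trees: int = 500,
        learning_rate: float = 0.1,
        max_depth: int = 3,
        seed: int = 0,
    ):
        self.n_trees = n_trees
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("training labels contain a single class")
        self._gbdt = GradientBoostingClassifier(
            n_estimators=self.n_trees,
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            random_state=self.seed,
        )
        self._gbdt.fit(X, y)
        self.classes_ = self._gbdt.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "_gbdt")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or (X.shape[0] and X.shape[1] != self.n_features_in_):
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1:]}"
            )
        return self._gbdt.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def score_pairs(self, X) -> np.ndarray:
        """Interaction probability per pair (larger = more likely DTI)."""
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] == 0:
            return np.empty(0)
        return self.predict_proba(X)[:, list(self.classes_).index(1)]


def train_classifier(train: PairDataset, cfg: GbdtConfig | None = None):
    cfg = cfg or GbdtConfig()
    clf = GBDTPairClassifier(
        n_trees=cfg.n_trees,
        learning_rate=cfg.learning_rate,
        max_depth=cfg.max_depth,
        seed=cfg.seed,
    )
    return clf.fit(train.features, train.labels)


def score_pairs(model: GBDTPairClassifier, test: PairDataset) -> np.ndarray:
    return model.score_pairs(test.features)


def call_interactions(scores: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """Binary calls: 1 iff score strictly exceeds the cutoff."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    return (np.asarray(scores) > cutoff).astype(np.int64)


def rank_candidates(
    scores: np.ndarray,
    pair_ids: list[tuple[str, str]],
    top_n: int | None = None,
) -> list[int]:
    """Indices of the top_n pairs by descending score.

    Ties are broken by (drug_id, target_id) lexicographic order so rankings
    are deterministic.
    """
    scores = np.asarray(scores)
    if top_n is None:
        top_n = scores.size
    if top_n > scores.size:
        raise ValueError(f"top_n={top_n} exceeds {scores.size} scored pairs")
    order = sorted(range(scores.size), key=lambda i: (-scores[i], pair_ids[i]))
    return order[:top_n]


def save_model(model: GBDTPairClassifier, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> GBDTPairClassifier:
    return joblib.load(path)
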