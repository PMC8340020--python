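"""Sequence-level validation: IGHV-family classification from embedded CDR3s.

The CDR3 has no overlap with the V segment, so any ability to predict the
adjacent germline IGHV family from the embedded, trimmed CDR3 reflects a real
compositional association.  The workflow: balance classes by down-sampling to
the same count per family, reduce dimensions with PCA (fit on the training
split only), and score decision-tree / random-forest / 3-NN classifiers by
macro-averaged F1 on a stratified 25% held-out split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigError, StratificationError

DEFAULT_FAMILIES = ("IGHV1", "IGHV3", "IGHV4")
DEFAULT_CLASSIFIERS = ("decision-tree", "random-forest", "knn")


@dataclass(frozen=True)
class SeqLevelConfig:
    families: tuple[str, ...] = DEFAULT_FAMILIES
    per_family_n: int = 1000
    reduce_dims: int = 10
    test_fraction: float = 0.25
    classifiers: tuple[str, ...] = DEFAULT_CLASSIFIERS
    knn_k: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_family_n < 1:
            raise ValueError("per_family_n must be >= 1")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


def balance_by_family(
    vectors: np.ndarray,
    labels: Sequence[str],
    cfg: SeqLevelConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Down-sample to exactly ``per_family_n`` members per configured family,
    uniformly without replacement (seeded)."""
    vectors = np.asarray(vectors)
    labels = np.asarray(labels)
    rng = np.random.default_rng(cfg.seed)
    keep: list[np.ndarray] = []
    for fam in cfg.families:
        idx = np.flatnonzero(labels == fam)
        if len(idx) < cfg.per_family_n:
            raise ConfigError(
                f"family {fam} has only {len(idx)} members; "
                f"per_family_n={cfg.per_family_n} is unachievable"
            )
        keep.append(rng.choice(idx, size=cfg.per_family_n, replace=False))
    order = np.concatenate(keep)
    return vectors[order], labels[order]


def reduce_pca(train: np.ndarray, test: np.ndarray, k: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Project both splits onto the first k principal components fit on
    the training split only."""
    train = np.asarray(train, dtype=float)
    if k > min(train.shape):
        raise ValueError(f"k={k} exceeds min(n_samples, n_features)={min(train.shape)}")
    pca = PCA(n_components=k, random_state=seed).fit(train)
    return pca.transform(train), pca.transform(np.asarray(test, dtype=float))


def _make_classifier(name: str, cfg: SeqLevelConfig):
    # tree ensembles at library defaults by design; only knn_k is configurable
    if name == "decision-tree":
        return DecisionTreeClassifier(random_state=cfg.seed)
    if name == "random-forest":
        return RandomForestClassifier(random_state=cfg.seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=cfg.knn_k)
    raise ValueError(f"unknown classifier {name!r}")


class VFamilyClassifier(ClassifierMixin, BaseEstimator):
    """PCA + one downstream classifier as a single sklearn estimator."""

    def __init__(
        self,
        classifier: str = "decision-tree",
        reduce_dims: int = 10,
        knn_k: int = 3,
        seed: int = 0,
    ) -> None:
        self.classifier = classifier
        self.reduce_dims = reduce_dims
        self.knn_k = knn_k
        self.seed = seed

    def fit(self, X, y):
        cfg = SeqLevelConfig(knn_k=self.knn_k, reduce_dims=self.reduce_dims, seed=self.seed)
        self.pipeline_ = Pipeline(
            [
                ("pca", PCA(n_components=self.reduce_dims, random_state=self.seed)),
                ("clf", _make_classifier(self.classifier, cfg)),
            ]
        )
        self.pipeline_.fit(X, y)
        self.classes_ = self.pipeline_.classes_
        return self

    def predict(self, X):
        return self.pipeline_.predict(X)


def train_eval_family_classifier(
    vectors: np.ndarray,
    labels: Sequence[str],
    cfg: SeqLevelConfig = SeqLevelConfig(),
) -> dict:
    """Stratified 75/25 split, PCA on train only, macro-F1 per classifier.

    Returns ``{"scores": {name: f1}, "manifest": {...}}`` where the manifest
    records the split indices so the evaluation is auditable.
    """
    vectors = np.asarray(vectors, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise StratificationError("need at least 2 families to classify")
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=cfg.test_fraction,
        stratify=labels,
        random_state=cfg.seed,
    )
    if set(labels[train_idx]) != set(labels):
        raise StratificationError("a class is absent from the training split")
    k = min(cfg.reduce_dims, vectors.shape[1], len(train_idx))
    tr, te = reduce_pca(vectors[train_idx], vectors[test_idx], k, seed=cfg.seed)
    scores = {}
    for name in cfg.classifiers:
        clf = _make_classifier(name, cfg)
        clf.fit(tr, labels[train_idx])
        scores[name] = float(f1_score(labels[test_idx], clf.predict(te), average="macro"))
    return {
        "scores": scores,
        "manifest": {
            "train_idx": train_idx.tolist(),
            "test_idx": test_idx.tolist(),
            "reduce_dims": k,
            "seed": cfg.seed,
        },
    }


def dimension_sweep(
    vectors: np.ndarray,
    labels: Sequence[str],
    dims: Sequence[int],
    cfg: SeqLevelConfig = SeqLevelConfig(),
) -> pd.DataFrame:
    """Repeat the evaluation across PCA dimensionalities using one fixed split."""
    rows = []
    for d in dims:
        res = train_eval_family_classifier(
            vectors, labels, SeqLevelConfig(
                families=cfg.families,
                per_family_n=cfg.per_family_n,
                reduce_dims=d,
                test_fraction=cfg.test_fraction,
                classifiers=cfg.classifiers,
                knn_k=cfg.knn_k,
                seed=cfg.seed,
            )
        )
        rows.append({"dim": d, **res["scores"]})
    return pd.DataFrame(rows, columns=["dim", *cfg.classifiers] if rows else ["dim"])
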