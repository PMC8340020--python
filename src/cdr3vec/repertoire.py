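"""Repertoire-level representation and two-cohort classification.

Embedded CDR3 vectors are grouped by (V gene, J gene, CDR3 length) —
approximate clonal partitions — then complete-linkage clustered within each
group at a data-driven threshold: 0.65 times the Euclidean norm of the
group's per-dimension standard-deviation vector.  Clusters failing quality
control (fewer than 10 sequences, or more than 90% from one subject) are
dropped.  Per-subject cluster frequencies drive a directional selection of
cohort-enriched clusters; the feature table holds squared per-subject counts
for the selected clusters; a random forest keeps the top-k most informative
columns and an L2 logistic regression does the final call.  Evaluation uses
repeated leave-one-subject-per-cohort-out cross-validation, with all
label-dependent steps (selection, ranking, fitting) redone inside every
training fold.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .airr_io import RearrangementRecord, get_gene
from .errors import ConfigError, VCallParseError


@dataclass(frozen=True)
class RepertoireClusteringConfig:
    threshold_factor: float = 0.65
    linkage: str = "complete"
    min_cluster_size: int = 10
    max_single_sample_fraction: float = 0.90

    def __post_init__(self) -> None:
        if self.threshold_factor <= 0:
            raise ValueError("threshold_factor must be > 0")
        if not 0 < self.max_single_sample_fraction <= 1:
            raise ValueError("max_single_sample_fraction must be in (0, 1]")
        if self.linkage != "complete":
            raise ValueError("only complete linkage is supported")


@dataclass
class VJLGroup:
    """All sequences sharing (V gene, J gene, CDR3 length)."""

    key: tuple[str, str, int]
    member_idx: list[int]


@dataclass
class SequenceCluster:
    """One linkage cluster inside a V/J/length group."""

    cluster_id: int
    key: tuple[str, str, int]
    member_idx: list[int]
    subject_counts: Counter = field(default_factory=Counter)
    has_multiread: bool = False

    @property
    def size(self) -> int:
        return len(self.member_idx)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_counts)


def group_by_vjl(
    records: Sequence[RearrangementRecord],
) -> tuple[list[VJLGroup], int]:
    """Partition record indices by (V gene, J gene, trimmed-CDR3 length).

    Gene = family-gene token without allele, first call wins.  Records with
    unparsable calls are excluded; their count is returned alongside.
    """
    groups: dict[tuple[str, str, int], list[int]] = {}
    n_excluded = 0
    for i, rec in enumerate(records):
        try:
            key = (get_gene(rec.v_call), get_gene(rec.j_call), len(rec.cdr3_aa or ""))
        except VCallParseError:
            n_excluded += 1
            continue
        groups.setdefault(key, []).append(i)
    return [VJLGroup(key=k, member_idx=v) for k, v in groups.items()], n_excluded


def cluster_group(
    group: VJLGroup,
    vectors: np.ndarray,
    records: Sequence[RearrangementRecord],
    cfg: RepertoireClusteringConfig = RepertoireClusteringConfig(),
    start_id: int = 0,
) -> list[SequenceCluster]:
    """Complete-linkage clustering of one group at t = factor * ||std vector||.

    The "std vector" holds the per-dimension standard deviations over the
    group's vectors; cutting the complete-linkage dendrogram at t guarantees
    the maximum pairwise distance within every returned cluster is <= t.
    """
    idx = np.asarray(group.member_idx)
    if len(idx) == 1:
        labels = np.array([1])
    else:
        sub = vectors[idx]
        std_vector = sub.std(axis=0, ddof=0)
        t = cfg.threshold_factor * float(np.linalg.norm(std_vector))
        dists = pdist(sub)
        if t == 0.0:
            # all vectors identical: every distance is 0 <= 0, one cluster
            labels = np.ones(len(idx), dtype=int)
        else:
            labels = fcluster(linkage(dists, method="complete"), t=t, criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        members = idx[labels == lab].tolist()
        counts = Counter(records[m].subject_id for m in members)
        clusters.append(
            SequenceCluster(
                cluster_id=start_id + len(clusters),
                key=group.key,
                member_idx=members,
                subject_counts=counts,
                has_multiread=any(records[m].duplicate_count > 1 for m in members),
            )
        )
    return clusters


def cluster_all_groups(
    records: Sequence[RearrangementRecord],
    vectors: np.ndarray,
    cfg: RepertoireClusteringConfig = RepertoireClusteringConfig(),
) -> list[SequenceCluster]:
    """Group by V/J/length and cluster every group; cluster ids are global."""
    groups, _ = group_by_vjl(records)
    clusters: list[SequenceCluster] = []
    for g in groups:
        clusters.extend(cluster_group(g, vectors, records, cfg, start_id=len(clusters)))
    return clusters


def qc_filter_clusters(
    clusters: Sequence[SequenceCluster],
    cfg: RepertoireClusteringConfig = RepertoireClusteringConfig(),
) -> tuple[list[SequenceCluster], dict[str, int]]:
    """Drop clusters smaller than ``min_cluster_size`` or with a strict
    majority share above ``max_single_sample_fraction`` from one subject."""
    kept = []
    report = {"size": 0, "dominance": 0}
    for cl in clusters:
        if cl.size < cfg.min_cluster_size:
            report["size"] += 1
        elif max(cl.subject_counts.values()) / cl.size > cfg.max_single_sample_fraction:
            report["dominance"] += 1
        else:
            kept.append(cl)
    return kept, report


def _cohort_freq_sums(
    cluster: SequenceCluster,
    subjects: Sequence[str],
    labels: Mapping[str, str],
    totals: Mapping[str, int],
    cohorts: tuple[str, str],
) -> tuple[float, float]:
    """Per cohort: sum over its subjects of (count_in_cluster / subject_total)^2."""
    sums = {cohorts[0]: 0.0, cohorts[1]: 0.0}
    for s in subjects:
        total = totals.get(s, 0)
        if total == 0:
            continue
        f = cluster.subject_counts.get(s, 0) / total
        sums[labels[s]] += f * f
    return sums[cohorts[0]], sums[cohorts[1]]


def select_discriminative_clusters(
    clusters: Sequence[SequenceCluster],
    labels: Mapping[str, str],
    totals: Mapping[str, int],
    margin: float = 0.5,
    direction: str = "both",
    subjects: Sequence[str] | None = None,
) -> list[int]:
    """Select clusters whose cohort squared-frequency sums differ by more than
    ``margin`` (strict), in the requested direction.

    Eligibility additionally requires members from more than one subject and
    at least one member observed in more than one raw read
    (duplicate_count > 1).  ``direction`` is ``"a>b"``, ``"b>a"`` or
    ``"both"`` with cohort A the first label in sorted order.
    """
    if subjects is None:
        subjects = sorted(labels)
    zero_total = [s for s in subjects if totals.get(s, 0) == 0]
    if zero_total:
        warnings.warn(f"subjects with zero sequences excluded: {zero_total}", stacklevel=2)
    cohorts = tuple(sorted(set(labels[s] for s in subjects)))
    if len(cohorts) != 2:
        raise ConfigError(f"need exactly two cohorts, got {cohorts}")
    selected = []
    for cl in clusters:
        if cl.n_subjects < 2 or not cl.has_multiread:
            continue
        a, b = _cohort_freq_sums(cl, subjects, labels, totals, cohorts)
        hit = False
        if direction in ("a>b", "both") and a - b > margin:
            hit = True
        if direction in ("b>a", "both") and b - a > margin:
            hit = True
        if hit:
            selected.append(cl.cluster_id)
    return selected


def build_feature_table(
    clusters: Sequence[SequenceCluster],
    selected_ids: Sequence[int],
    subjects: Sequence[str],
    labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Subjects x selected-clusters table of squared per-subject counts."""
    by_id = {cl.cluster_id: cl for cl in clusters}
    data = {
        cid: [by_id[cid].subject_counts.get(s, 0) ** 2 for s in subjects]
        for cid in selected_ids
    }
    table = pd.DataFrame(data, index=list(subjects), columns=list(selected_ids))
    if labels is not None:
        table.attrs["labels"] = {s: labels[s] for s in subjects}
    return table


def select_top_features_rf(
    table: pd.DataFrame,
    y: Sequence[str],
    k: int = 18,
    seed: int = 0,
) -> pd.DataFrame:
    """Keep the k columns with highest random-forest impurity importance.

    With k or fewer columns the table is returned unchanged (with a warning
    when strictly fewer)."""
    if table.shape[1] <= k:
        if table.shape[1] < k:
            warnings.warn(
                f"only {table.shape[1]} features available; keeping all (k={k})",
                stacklevel=2,
            )
        return table
    rf = RandomForestClassifier(random_state=seed).fit(table.to_numpy(), np.asarray(y))
    order = np.argsort(rf.feature_importances_)[::-1][:k]
    return table.iloc[:, np.sort(order)]


class RepertoireClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest top-k feature elimination followed by L2 logistic
    regression (C=0.003), as one sklearn estimator over a squared-count
    feature table."""

    def __init__(self, top_k: int = 18, C: float = 0.003, seed: int = 0) -> None:
        self.top_k = top_k
        self.C = C
        self.seed = seed

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        reduced = select_top_features_rf(X, y, k=self.top_k, seed=self.seed)
        self.feature_ids_ = list(reduced.columns)
        # sklearn's default penalty is the L2 norm we want
        self.lr_ = LogisticRegression(C=self.C, max_iter=1000)
        self.lr_.fit(reduced.to_numpy(), y)
        self.classes_ = self.lr_.classes_
        return self

    def predict(self, X: pd.DataFrame):
        X = pd.DataFrame(X)
        return self.lr_.predict(X[self.feature_ids_].to_numpy())


def classify_repertoires_cv(
    clusters: Sequence[SequenceCluster],
    labels: Mapping[str, str],
    totals: Mapping[str, int],
    repeats: int = 100,
    margin: float = 0.5,
    direction: str = "both",
    top_k: int = 18,
    C: float = 0.003,
    seed: int = 0,
    shuffle_labels: bool = False,
) -> dict:
    """Repeated leave-one-subject-per-cohort-out cross-validation.

    Each repeat holds out one randomly drawn subject per cohort, reruns
    cluster selection and feature elimination on the remaining subjects only,
    fits the logistic regression, and predicts the two held-out subjects.
    Accuracy = correct predictions / (2 * repeats).  With
    ``shuffle_labels=True`` the training labels are permuted per repeat
    (held-out truth kept) as an overfitting control.  A fold whose training
    data selects no cluster falls back to predicting the first cohort for
    both held-out subjects.
    """
    subjects = sorted(labels)
    cohorts = tuple(sorted(set(labels.values())))
    if len(cohorts) != 2:
        raise ConfigError(f"need exactly two cohorts, got {cohorts}")
    by_cohort = {c: [s for s in subjects if labels[s] == c] for c in cohorts}
    if min(len(v) for v in by_cohort.values()) < 2:
        raise ConfigError("each cohort needs at least 2 subjects for CV")
    rng = np.random.default_rng(seed)
    outcomes = []
    for rep in range(repeats):
        test = [by_cohort[c][rng.integers(len(by_cohort[c]))] for c in cohorts]
        train = [s for s in subjects if s not in test]
        if shuffle_labels:
            shuffled = rng.permutation([labels[s] for s in train])
            train_labels = dict(zip(train, shuffled))
        else:
            train_labels = {s: labels[s] for s in train}
        correct = 0
        try:
            selected = select_discriminative_clusters(
                clusters, train_labels, totals,
                margin=margin, direction=direction, subjects=train,
            )
        except ConfigError:
            selected = []
        if not selected or len(set(train_labels.values())) < 2:
            preds = [cohorts[0], cohorts[0]]
        else:
            table = build_feature_table(clusters, selected, train)
            y = np.array([train_labels[s] for s in train])
            model = RepertoireClassifier(top_k=top_k, C=C, seed=seed + rep).fit(table, y)
            test_table = build_feature_table(clusters, selected, test)
            preds = list(model.predict(test_table))
        for subj, pred in zip(test, preds):
            correct += int(pred == labels[subj])
        outcomes.append(
            {"repeat": rep, "test_subjects": test, "predictions": [str(p) for p in preds],
             "n_selected": len(selected), "n_correct": correct}
        )
    accuracy = sum(o["n_correct"] for o in outcomes) / (2 * repeats)
    return {"accuracy": accuracy, "outcomes": outcomes, "cohorts": cohorts}
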