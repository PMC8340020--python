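"""V/J/length grouping, linkage clustering, QC, feature selection, CV."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from cdr3vec.airr_io import RearrangementRecord
from cdr3vec.errors import ConfigError
from cdr3vec.repertoire import (
    RepertoireClusteringConfig,
    SequenceCluster,
    VJLGroup,
    build_feature_table,
    classify_repertoires_cv,
    cluster_group,
    group_by_vjl,
    qc_filter_clusters,
    select_discriminative_clusters,
    select_top_features_rf,
)


def _rec(i, v="IGHV3-23*01", j="IGHJ4*02", aa="ARDFWSGY", subject="s1", dup=1):
    return RearrangementRecord(
        sequence_id=f"r{i}", v_call=v, j_call=j, cdr3_aa=aa,
        subject_id=subject, duplicate_count=dup,
    )


def _cluster(cid, counts, size=None, multiread=True):
    counts = Counter(counts)
    members = list(range(size or sum(counts.values())))
    return SequenceCluster(
        cluster_id=cid, key=("IGHV3-23", "IGHJ4", 15),
        member_idx=members, subject_counts=counts, has_multiread=multiread,
    )


class TestGrouping:
    def test_partition_by_v_j_length(self):
        records = [
            _rec(0, aa="AAAAA"), _rec(1, aa="CCCCC"), _rec(2, aa="AAAAAA"),
        ]
        groups, excluded = group_by_vjl(records)
        assert excluded == 0
        keys = sorted(g.key for g in groups)
        assert keys == [("IGHV3-23", "IGHJ4", 5), ("IGHV3-23", "IGHJ4", 6)]
        assert sum(len(g.member_idx) for g in groups) == 3

    def test_alleles_share_group(self):
        records = [_rec(0, v="IGHV3-23*01"), _rec(1, v="IGHV3-23*02")]
        groups, _ = group_by_vjl(records)
        assert len(groups) == 1

    def test_empty_and_unparsable(self):
        assert group_by_vjl([]) == ([], 0)
        groups, excluded = group_by_vjl([_rec(0, v="garbage")])
        assert groups == [] and excluded == 1


class TestClusterGroup:
    def brute_force_complete_linkage_ok(self, vectors, members_lists, t):
        """Check the complete-linkage guarantee directly."""
        for members in members_lists:
            sub = vectors[members]
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    assert np.linalg.norm(sub[i] - sub[j]) <= t + 1e-9

    def test_identical_vectors_single_cluster(self):
        records = [_rec(i) for i in range(5)]
        vectors = np.ones((5, 4))
        group = VJLGroup(key=("IGHV3-23", "IGHJ4", 8), member_idx=list(range(5)))
        clusters = cluster_group(group, vectors, records)
        assert len(clusters) == 1 and clusters[0].size == 5

    def test_two_separated_blobs_two_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.05, size=(10, 6))
        b = rng.normal(0, 0.05, size=(10, 6)) + 50.0
        vectors = np.vstack([a, b])
        records = [_rec(i, subject=f"s{i%3}") for i in range(20)]
        group = VJLGroup(key=("IGHV3-23", "IGHJ4", 8), member_idx=list(range(20)))
        cfg = RepertoireClusteringConfig()
        clusters = cluster_group(group, vectors, records, cfg)
        assert len(clusters) == 2
        assert sorted(c.size for c in clusters) == [10, 10]
        std_norm = np.linalg.norm(vectors.std(axis=0))
        self.brute_force_complete_linkage_ok(
            vectors, [c.member_idx for c in clusters], cfg.threshold_factor * std_norm
        )

    def test_singleton_group(self):
        records = [_rec(0)]
        clusters = cluster_group(
            VJLGroup(key=("IGHV3-23", "IGHJ4", 8), member_idx=[0]),
            np.ones((1, 4)), records,
        )
        assert len(clusters) == 1 and clusters[0].size == 1

    def test_complete_linkage_guarantee_random_groups(self):
        rng = np.random.default_rng(1)
        cfg = RepertoireClusteringConfig()
        for trial in range(30):
            m = int(rng.integers(3, 40))
            vectors = rng.normal(size=(m, 8)) * rng.uniform(0.5, 3)
            records = [_rec(i, subject=f"s{i%4}") for i in range(m)]
            group = VJLGroup(key=("IGHV3-23", "IGHJ4", 8), member_idx=list(range(m)))
            clusters = cluster_group(group, vectors, records, cfg)
            t = cfg.threshold_factor * np.linalg.norm(vectors.std(axis=0))
            self.brute_force_complete_linkage_ok(
                vectors, [c.member_idx for c in clusters], t
            )
            assert sum(c.size for c in clusters) == m


class TestQCFilter:
    def test_size_rule(self):
        kept, report = qc_filter_clusters([_cluster(0, {"a": 5, "b": 4})])
        assert kept == [] and report["size"] == 1

    def test_dominance_rule(self):
        kept, report = qc_filter_clusters([_cluster(0, {"a": 19, "b": 1})])
        assert kept == [] and report["dominance"] == 1

    def test_exact_ninety_percent_kept(self):
        kept, _ = qc_filter_clusters([_cluster(0, {"a": 9, "b": 1})])
        assert len(kept) == 1  # 90% exactly is not "more than 90%"

    def test_mixed_set(self):
        clusters = [
            _cluster(0, {"a": 6, "b": 6}),   # kept
            _cluster(1, {"a": 9}),            # size < 10
            _cluster(2, {"a": 19, "b": 1}),   # dominance 95%
        ]
        kept, report = qc_filter_clusters(clusters)
        assert [c.cluster_id for c in kept] == [0]
        assert report == {"size": 1, "dominance": 1}


class TestSelection:
    labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    totals = {"a1": 10, "a2": 10, "b1": 10, "b2": 10}

    def test_margin_exceeded_selected(self):
        # A subjects hold most of their repertoires in the cluster
        cl = _cluster(0, {"a1": 7, "a2": 6, "b1": 2, "b2": 2})
        sel = select_discriminative_clusters([cl], self.labels, self.totals, margin=0.5)
        # sums: A = 0.49 + 0.36 = 0.85, B = 0.04 + 0.04 = 0.08 -> 0.77 > 0.5
        assert sel == [0]

    def test_margin_exactly_met_not_selected(self):
        labels = {"a1": "A", "b1": "B", "a2": "A", "b2": "B"}
        totals = {"a1": 10, "a2": 10, "b1": 10, "b2": 10}
        # A sum: (5/10)^2 * 2 = 0.5, B sum 0 -> difference exactly 0.5
        cl = _cluster(0, {"a1": 5, "a2": 5})
        assert select_discriminative_clusters([cl], labels, totals, margin=0.5) == []

    def test_single_subject_cluster_never_selected(self):
        cl = _cluster(0, {"a1": 10})
        assert (
            select_discriminative_clusters([cl], self.labels, self.totals, margin=0.0)
            == []
        )

    def test_requires_multiread_member(self):
        cl = _cluster(0, {"a1": 7, "a2": 6}, multiread=False)
        assert (
            select_discriminative_clusters([cl], self.labels, self.totals, margin=0.0)
            == []
        )

    def test_direction_flag(self):
        cl = _cluster(0, {"b1": 7, "b2": 6})
        kw = dict(labels=self.labels, totals=self.totals, margin=0.5)
        assert select_discriminative_clusters([cl], **kw) == [0]  # both
        assert (
            select_discriminative_clusters([cl], direction="a>b", **kw) == []
        )
        assert select_discriminative_clusters([cl], direction="b>a", **kw) == [0]


class TestFeatureTable:
    def test_cells_are_squared_counts(self):
        cl = _cluster(3, {"a1": 3, "b1": 1})
        table = build_feature_table([cl], [3], ["a1", "a2", "b1"])
        assert table.shape == (3, 1)
        assert table.loc["a1", 3] == 9
        assert table.loc["a2", 3] == 0
        assert table.loc["b1", 3] == 1

    def test_shape_n_by_m(self):
        clusters = [_cluster(i, {"a1": i + 1}) for i in range(4)]
        table = build_feature_table(clusters, [0, 1, 2, 3], ["a1", "b1"])
        assert table.shape == (2, 4)


class TestTopFeaturesRF:
    def test_m_equal_k_unchanged(self):
        table = pd.DataFrame(np.ones((6, 3)), columns=[10, 11, 12])
        out = select_top_features_rf(table, ["A", "A", "A", "B", "B", "B"], k=3)
        assert list(out.columns) == [10, 11, 12]

    def test_fewer_than_k_warns(self):
        table = pd.DataFrame(np.ones((4, 2)))
        with pytest.warns(UserWarning):
            out = select_top_features_rf(table, ["A", "A", "B", "B"], k=18)
        assert out.shape[1] == 2

    def test_planted_informative_column_survives(self):
        rng = np.random.default_rng(2)
        y = np.array(["A"] * 10 + ["B"] * 10)
        hits = 0
        for seed in range(5):
            X = pd.DataFrame(rng.normal(size=(20, 30)))
            X[7] = np.where(y == "A", 5.0, -5.0) + rng.normal(scale=0.1, size=20)
            out = select_top_features_rf(X, y, k=5, seed=seed)
            hits += 7 in out.columns
        assert hits >= 4


class TestRepertoireCV:
    def _planted_setup(self, n_per_cohort=5, strength=8):
        labels, totals = {}, {}
        counts = {}
        rng = np.random.default_rng(3)
        for c, coh in enumerate("AB"):
            for i in range(n_per_cohort):
                s = f"{coh}{i}"
                labels[s] = coh
                totals[s] = 100
                counts[s] = strength + int(rng.integers(3)) if coh == "A" else 1
        cl = _cluster(0, counts)
        noise = [
            _cluster(i + 1, {s: int(rng.integers(1, 5)) for s in labels})
            for i in range(4)
        ]
        return [cl, *noise], labels, totals

    def test_separable_cohorts_high_accuracy(self):
        clusters, labels, totals = self._planted_setup()
        res = classify_repertoires_cv(
            clusters, labels, totals, repeats=20, margin=0.0, seed=0
        )
        assert res["accuracy"] > 0.9

    def test_shuffled_labels_near_chance(self):
        clusters, labels, totals = self._planted_setup()
        res = classify_repertoires_cv(
            clusters, labels, totals, repeats=40, margin=0.0, seed=0,
            shuffle_labels=True,
        )
        # binomial 95% CI around 0.5 with 80 draws
        assert abs(res["accuracy"] - 0.5) < 0.15

    def test_single_subject_cohort_rejected(self):
        clusters, labels, totals = self._planted_setup(n_per_cohort=1)
        with pytest.raises(ConfigError):
            classify_repertoires_cv(clusters, labels, totals, repeats=2)

    def test_accuracy_bookkeeping(self):
        clusters, labels, totals = self._planted_setup()
        res = classify_repertoires_cv(
            clusters, labels, totals, repeats=7, margin=0.0, seed=1
        )
        assert len(res["outcomes"]) == 7
        total_correct = sum(o["n_correct"] for o in res["outcomes"])
        assert res["accuracy"] == total_correct / 14
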