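"""Unsupervised-RF proximity clustering and shallow/deep labeling."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from phyloclone.classify import (
    _kmeans_proximity,
    classify_cohort,
    cluster_consensus,
    label_clusters,
    rf_proximity,
    synthetic_class2,
)
from phyloclone.features import FEATURE_ORDER, features_frame
from phyloclone.simulate import simulate_tree


class TestSyntheticClass2:
    def test_constant_column_preserved(self, rng):
        X = np.column_stack([np.full(20, 3.14), rng.normal(size=20)])
        X2 = synthetic_class2(X, rng)
        assert (X2[:, 0] == 3.14).all()

    def test_support_preserved(self, rng):
        X = rng.normal(size=(30, 4))
        X2 = synthetic_class2(X, rng)
        for j in range(4):
            assert set(X2[:, j]) <= set(X[:, j])

    def test_destroys_dependence(self):
        """Strongly correlated input columns become uncorrelated on average."""
        base_rng = np.random.default_rng(0)
        x = base_rng.normal(size=200)
        X = np.column_stack([x, x + 0.01 * base_rng.normal(size=200)])
        assert abs(spearmanr(X[:, 0], X[:, 1]).statistic) > 0.99
        rhos = []
        for s in range(100):
            X2 = synthetic_class2(X, np.random.default_rng(s))
            rhos.append(spearmanr(X2[:, 0], X2[:, 1]).statistic)
        assert abs(np.mean(rhos)) < 0.1


class TestProximity:
    def test_diagonal_and_symmetry(self, rng):
        X = rng.normal(size=(12, 5))
        P = rf_proximity(X, rng, n_trees=100)
        assert np.allclose(np.diag(P), 1.0)
        assert np.allclose(P, P.T)
        assert (P >= 0).all() and (P <= 1).all()

    def test_duplicated_rows_maximal_proximity(self):
        """Identical points are always co-terminal, so their proximity
        dominates every other pair involving them."""
        wins = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            X = rng.normal(size=(10, 3))
            X[1] = X[0]  # duplicate pair
            P = rf_proximity(X, rng, n_trees=100)
            others = np.concatenate([np.delete(P[0], [0, 1]), np.delete(P[1], [0, 1])])
            wins += P[0, 1] >= others.max()
        assert wins == 20

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            rf_proximity(np.zeros((3, 2)), rng)


class TestKMeansOnProximity:
    def test_perfect_block_matrix_recovers_blocks(self, rng):
        P = np.zeros((10, 10))
        P[:5, :5] = 1.0
        P[5:, 5:] = 1.0
        lab, ss = _kmeans_proximity(P, rng)
        assert len(set(lab[:5])) == 1 and len(set(lab[5:])) == 1
        assert lab[0] != lab[5]
        assert ss == pytest.approx(0.0, abs=1e-9)


class TestLabeling:
    def _features(self, me, pe, assignment):
        n = len(assignment)
        df = pd.DataFrame(0.5, index=[f"s{i}" for i in range(n)],
                          columns=list(FEATURE_ORDER))
        df["ME"] = me
        df["PE"] = pe
        return df

    def test_higher_maximum_is_deep(self):
        assign = np.array([1, 1, 2, 2])
        feats = self._features([0.95, 0.95, 0.60, 0.60], [0.90, 0.90, 0.70, 0.70], assign)
        res = label_clusters(assign, feats)
        assert list(res.labels) == ["deep", "deep", "shallow", "shallow"]
        assert res.m1 == pytest.approx(0.95)
        assert res.m2 == pytest.approx(0.70)

    def test_label_invariant_to_cluster_index_swap(self):
        feats = self._features([0.95, 0.95, 0.60, 0.60], [0.90, 0.90, 0.70, 0.70],
                               np.array([1, 1, 2, 2]))
        a = label_clusters(np.array([1, 1, 2, 2]), feats)
        b = label_clusters(np.array([2, 2, 1, 1]), feats)
        assert list(a.labels) == list(b.labels)

    def test_exact_tie_broken_by_mean_pe_then_index(self):
        assign = np.array([1, 1, 2, 2])
        feats = self._features([0.8, 0.8, 0.7, 0.7], [0.7, 0.7, 0.8, 0.8], assign)
        with pytest.warns(UserWarning):
            res = label_clusters(assign, feats)  # maxima both 0.8; PE favors cluster 2
        assert list(res.labels) == ["shallow", "shallow", "deep", "deep"]

    def test_empty_cluster_rejected(self):
        feats = self._features([0.9] * 4, [0.9] * 4, np.ones(4, dtype=int))
        with pytest.raises(ValueError):
            label_clusters(np.ones(4, dtype=int), feats)


class TestConsensusClustering:
    def _cohort_features(self, rng, n_per=25):
        trees = []
        truth = []
        for i in range(n_per):
            trees.append(simulate_tree("deep", int(rng.integers(3, 6)), rng,
                                       balance_alpha=50.0, sample_id=f"d{i}"))
            truth.append("deep")
        for i in range(n_per):
            trees.append(simulate_tree("shallow", int(rng.integers(3, 6)), rng,
                                       balance_alpha=0.3, sample_id=f"s{i}"))
            truth.append("shallow")
        return features_frame(trees), np.array(truth)

    def test_recovers_balanced_vs_skewed(self, rng):
        feats, truth = self._cohort_features(rng)
        X = feats[list(FEATURE_ORDER)].to_numpy()
        assign, _ = cluster_consensus(X, rng, n_augment=3, n_trees=150)
        labels = label_clusters(assign, feats).labels
        assert (labels == truth).mean() >= 0.9

    def test_permutation_equivariance(self, rng):
        feats, _ = self._cohort_features(rng, n_per=10)
        X = feats[list(FEATURE_ORDER)].to_numpy()
        a, _ = cluster_consensus(X, np.random.default_rng(7), n_augment=2, n_trees=60)
        perm = np.random.default_rng(3).permutation(len(X))
        b, _ = cluster_consensus(X[perm], np.random.default_rng(7), n_augment=2, n_trees=60)
        # same partition after permuting back (cluster ids may swap)
        agree = (a[perm] == b).mean()
        assert agree in (0.0, 1.0)

    def test_duplicated_samples_co_cluster(self, rng):
        feats, _ = self._cohort_features(rng, n_per=8)
        X = feats[list(FEATURE_ORDER)].to_numpy()
        X[1] = X[0]
        assign, _ = cluster_consensus(X, rng, n_augment=2, n_trees=100)
        assert assign[0] == assign[1]


class TestClassifyCohort:
    def test_all_linear_cohort_skips_clustering(self, rng):
        trees = [simulate_tree("linear", int(rng.integers(1, 5)), rng, sample_id=f"l{i}")
                 for i in range(10)]
        df, res = classify_cohort(trees, rng)
        assert (df["label"] == "linear").all()
        assert res is None

    def test_too_few_nonlinear_marked_unresolved(self, rng):
        trees = [simulate_tree("linear", 3, rng, sample_id=f"l{i}") for i in range(6)]
        trees += [simulate_tree("deep", 4, rng, sample_id=f"d{i}") for i in range(2)]
        with pytest.warns(UserWarning):
            df, _ = classify_cohort(trees, rng)
        assert set(df["label"]) <= {"linear", "shallow", "deep", "nonlinear-unresolved"}
        assert (df["label"] == "nonlinear-unresolved").sum() == 2

    def test_mixed_cohort_label_set_and_deep_mean_rule(self, rng):
        trees = []
        for label in ("linear", "shallow", "deep"):
            lo = 2 if label == "linear" else 3
            trees += [simulate_tree(label, int(rng.integers(lo, 6)), rng,
                                    sample_id=f"{label}{i}") for i in range(15)]
        df, res = classify_cohort(trees, rng, n_augment=2, n_trees=100)
        assert set(df["label"]) <= {"linear", "shallow", "deep"}
        # deep-labeled cluster dominates by construction of the m-rule
        assert max(res.cluster_means[1]["ME"], res.cluster_means[1]["PE"]) != \
               max(res.cluster_means[2]["ME"], res.cluster_means[2]["PE"])
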