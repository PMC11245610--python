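"""Shallow- vs deep-branching classification of nonlinear trees.

Follows the classical unsupervised random-forest recipe: the real feature
rows are class 1 and a synthetic class 2 of the same size is drawn from the
univariate feature marginals (destroying the dependence structure). A
forest trained to separate the two yields a proximity matrix — the
fraction of trees in which two real rows share a terminal node — whose rows
are clustered with k-means (centers=2, nstart=20, iter.max=10). The
augmentation is repeated and the assignment with the lowest within-cluster
sum of squares kept. Clusters are labeled by m_k = max(mean ME, mean PE):
the cluster with the larger maximum is deep branching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier

from .features import features_frame
from .inference import classify_linearity
from .trees import ClonalTree

LABEL_SET = ("linear", "shallow", "deep", "nonlinear-unresolved")


@dataclass
class ClusterResult:
    assignment: np.ndarray  # cluster index 1/2 per sample
    labels: np.ndarray  # "shallow"/"deep" per sample
    cluster_means: dict[int, dict[str, float]]
    m1: float
    m2: float
    within_ss: float
    seed: int


def synthetic_class2(features: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Each column resampled independently with replacement from its own
    empirical values; marginals preserved, dependence destroyed."""
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[:, j] = X[rng.integers(0, n, size=n), j]
    return out


def rf_proximity(
    features: np.ndarray,
    rng: np.random.Generator,
    n_trees: int = 1000,
) -> np.ndarray:
    """Proximity matrix of the real rows from a forest trained to separate
    them from their synthetic class-2 counterpart."""
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X2 = synthetic_class2(X, rng)
    Xa = np.vstack([X, X2])
    y = np.r_[np.zeros(n), np.ones(n)]
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max(1, round(np.sqrt(X.shape[1]))),
        min_samples_leaf=1,
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    forest.fit(Xa, y)
    leaves = forest.apply(X)  # n x n_trees terminal-node ids
    prox = (leaves[:, None, :] == leaves[None, :, :]).mean(axis=2)
    return prox


def _kmeans_proximity(
    prox: np.ndarray,
    rng: np.random.Generator,
    centers: int = 2,
    nstart: int = 20,
    iter_max: int = 10,
) -> tuple[np.ndarray, float]:
    """k-means on proximity rows as coordinate vectors; returns
    (assignment, within-cluster sum of squares). A run with an empty
    cluster is re-initialized."""
    for _ in range(20):
        km = KMeans(
            n_clusters=centers,
            init="random",
            n_init=nstart,
            max_iter=iter_max,
            random_state=int(rng.integers(2**31 - 1)),
        )
        lab = km.fit_predict(prox)
        if len(np.unique(lab)) == centers:
            return lab, float(km.inertia_)
    raise RuntimeError("k-means kept producing an empty cluster")


def cluster_consensus(
    features: np.ndarray,
    rng: np.random.Generator,
    n_augment: int = 20,
    centers: int = 2,
    nstart: int = 20,
    iter_max: int = 10,
    n_trees: int = 1000,
) -> tuple[np.ndarray, float]:
    """Consensus over repeated augmentations: the assignment with the
    lowest total within-cluster sum of squares wins.

    Rows are processed in a canonical (lexicographic) order internally, so
    the result is exactly equivariant under permutations of the input rows
    for a fixed seed.
    """
    X = np.asarray(features, dtype=float)
    order = np.lexsort(X.T[::-1])
    Xs = X[order]
    best_lab: np.ndarray | None = None
    best_ss = np.inf
    for _ in range(n_augment):
        prox = rf_proximity(Xs, rng, n_trees=n_trees)
        lab, ss = _kmeans_proximity(prox, rng, centers, nstart, iter_max)
        if ss < best_ss:
            best_ss, best_lab = ss, lab
    assert best_lab is not None
    out = np.empty(len(X), dtype=int)
    out[order] = best_lab
    return out, best_ss


def label_clusters(
    assignment: np.ndarray,
    features: pd.DataFrame,
    within_ss: float = float("nan"),
    seed: int = 0,
) -> ClusterResult:
    """Deep branching = the cluster whose max(mean ME, mean PE) is larger;
    ties broken by larger mean PE, then lower cluster index."""
    assignment = np.asarray(assignment)
    clusters = np.unique(assignment)
    if len(clusters) != 2 or any((assignment == c).sum() == 0 for c in clusters):
        raise ValueError("need exactly 2 non-empty clusters")
    means: dict[int, dict[str, float]] = {}
    for ci, c in enumerate(clusters, start=1):
        sub = features.loc[np.asarray(assignment == c)]
        means[ci] = {"ME": float(sub["ME"].mean()), "PE": float(sub["PE"].mean())}
    m = {ci: max(v["ME"], v["PE"]) for ci, v in means.items()}
    if m[1] > m[2]:
        deep = 1
    elif m[2] > m[1]:
        deep = 2
    else:  # exact tie: larger mean PE, then lower cluster index
        warnings.warn("cluster maxima tied exactly; breaking by mean PE then index")
        deep = 1 if means[1]["PE"] >= means[2]["PE"] else 2
    labels = np.where(assignment == clusters[deep - 1], "deep", "shallow")
    return ClusterResult(
        assignment=np.where(assignment == clusters[0], 1, 2),
        labels=labels,
        cluster_means=means,
        m1=m[1],
        m2=m[2],
        within_ss=within_ss,
        seed=seed,
    )


def classify_cohort(
    trees: list[ClonalTree],
    rng: np.random.Generator | None = None,
    n_augment: int = 20,
    n_trees: int = 1000,
    nstart: int = 20,
    iter_max: int = 10,
) -> tuple[pd.DataFrame, ClusterResult | None]:
    """Label every tree linear / shallow / deep.

    Linear trees are labeled directly from their topology; nonlinear trees
    are clustered and labeled by the m1/m2 rule. Fewer than 4 nonlinear
    trees cannot be clustered and are labeled 'nonlinear-unresolved'.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    seed = int(rng.integers(2**31 - 1))
    rng = np.random.default_rng(seed)
    linearity = np.array([classify_linearity(t) for t in trees])
    labels = np.array(["linear"] * len(trees), dtype=object)
    nonlin = np.flatnonzero(linearity == "nonlinear")
    result: ClusterResult | None = None
    if 0 < len(nonlin) < 4:
        warnings.warn("fewer than 4 nonlinear trees; labeling them unresolved")
        labels[nonlin] = "nonlinear-unresolved"
    elif len(nonlin) >= 4:
        feats = features_frame([trees[i] for i in nonlin], normalized=True)
        X = feats[list(feats.columns[:9])].to_numpy()
        assign, ss = cluster_consensus(
            X, rng, n_augment=n_augment, n_trees=n_trees, nstart=nstart, iter_max=iter_max
        )
        result = label_clusters(assign, feats, within_ss=ss, seed=seed)
        labels[nonlin] = result.labels
    cluster = np.zeros(len(trees), dtype=int)  # 0 = not clustered (linear/unresolved)
    if result is not None:
        cluster[nonlin] = result.assignment
    df = pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in trees],
            "label": labels,
            "linearity": linearity,
            "cluster": cluster,
            "seed": seed,
        }
    ).set_index("sample_id")
    return df, result
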