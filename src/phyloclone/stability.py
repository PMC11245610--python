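"""Bootstrap stability of the shallow/deep clustering.

Each replicate resamples the feature rows with replacement, reruns the
clustering-plus-labeling pipeline on the replicate, and cross-tabulates the
original labels of the resampled indices against the replicate labels in a
2x2 table. The affinity score of a replicate is the log odds ratio of that
table with a Haldane-Anscombe +0.5 in every cell, which keeps every score
finite; because the m1/m2 labeling makes the table orientation canonical,
perfect agreement always scores positively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import cluster_consensus, label_clusters


@dataclass
class StabilityReport:
    B: int
    scores: np.ndarray
    mean_score: float
    p_values: np.ndarray
    tables: list[np.ndarray]
    seed: int


def affinity_score(table: np.ndarray) -> float:
    """Corrected log odds ratio log((a+.5)(d+.5) / ((b+.5)(c+.5)))."""
    t = np.asarray(table, dtype=float) + 0.5
    return float(np.log(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0])))


def _crosstab(orig: np.ndarray, rep: np.ndarray) -> np.ndarray:
    """2x2 counts over {shallow, deep} x {shallow, deep}, duplicates with
    multiplicity."""
    cats = ("shallow", "deep")
    out = np.zeros((2, 2), dtype=int)
    for i, a in enumerate(cats):
        for j, b in enumerate(cats):
            out[i, j] = int(((orig == a) & (rep == b)).sum())
    return out


def _permutation_pvalue(
    orig: np.ndarray, rep: np.ndarray, score: float, rng: np.random.Generator, n_perm: int
) -> float:
    """Share of label permutations (replicate labels shuffled, margins
    preserved) scoring at least the observed value."""
    count = 0
    for _ in range(n_perm):
        if affinity_score(_crosstab(orig, rng.permutation(rep))) >= score:
            count += 1
    return count / n_perm


def bootstrap_replicate(
    features: pd.DataFrame,
    original_labels: np.ndarray,
    rng: np.random.Generator,
    n_trees: int = 1000,
    n_augment: int = 1,
    nstart: int = 20,
    iter_max: int = 10,
) -> tuple[np.ndarray, float]:
    """One bootstrap replicate: resample rows, rerun synthetic class ->
    forest -> k-means -> m1/m2 labeling, and score agreement."""
    n = len(features)
    if n < 4:
        raise ValueError("need at least 4 samples")
    idx = rng.integers(0, n, size=n)
    fb = features.iloc[idx]
    X = fb[list(fb.columns[:9])].to_numpy()
    assign, ss = cluster_consensus(
        X, rng, n_augment=n_augment, n_trees=n_trees, nstart=nstart, iter_max=iter_max
    )
    rep_labels = label_clusters(assign, fb, within_ss=ss).labels
    table = _crosstab(np.asarray(original_labels)[idx], rep_labels)
    return table, affinity_score(table)


def stability_run(
    features: pd.DataFrame,
    original_labels: np.ndarray,
    B: int = 1000,
    rng: np.random.Generator | None = None,
    n_trees: int = 1000,
    n_augment: int = 1,
    n_perm: int = 200,
) -> StabilityReport:
    """B bootstrap replicates with per-replicate permutation p-values."""
    if B < 1:
        raise ValueError("B must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    seed = int(rng.integers(2**31 - 1))
    rng = np.random.default_rng(seed)
    original_labels = np.asarray(original_labels)
    scores, pvals, tables = [], [], []
    for _ in range(B):
        idx_rng = rng  # shared stream keeps the whole run reproducible
        n = len(features)
        idx = idx_rng.integers(0, n, size=n)
        fb = features.iloc[idx]
        X = fb[list(fb.columns[:9])].to_numpy()
        assign, ss = cluster_consensus(
            X, rng, n_augment=n_augment, n_trees=n_trees
        )
        rep_labels = label_clusters(assign, fb, within_ss=ss).labels
        table = _crosstab(original_labels[idx], rep_labels)
        score = affinity_score(table)
        scores.append(score)
        tables.append(table)
        pvals.append(
            _permutation_pvalue(original_labels[idx], rep_labels, score, rng, n_perm)
        )
    scores_arr = np.asarray(scores)
    return StabilityReport(
        B=B,
        scores=scores_arr,
        mean_score=float(scores_arr.mean()),
        p_values=np.asarray(pvals),
        tables=tables,
        seed=seed,
    )
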