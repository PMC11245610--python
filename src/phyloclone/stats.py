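"""Outcome statistics: survival, immune composition, signature exposures.

The k-group log-rank statistic (with the hypergeometric variance under
ties) and its cohort-stratified form are implemented directly — the
stratified variant sums within-stratum observed-minus-expected vectors and
covariance matrices before forming the chi-square. Kruskal-Wallis delegates
to scipy; the mutational-signature comparison is a label-permutation test
on the absolute difference of group means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float


def _logrank_components(
    time: np.ndarray, event: np.ndarray, group_idx: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """(O - E, V) summed over event times for one stratum."""
    z = np.zeros(k)
    V = np.zeros((k, k))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        if n < 2:
            continue
        d = int(((time == t) & (event == 1)).sum())
        ng = np.bincount(group_idx[at_risk], minlength=k).astype(float)
        dg = np.bincount(group_idx[(time == t) & (event == 1)], minlength=k).astype(float)
        z += dg - d * ng / n
        frac = ng / n
        V += d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
    return z, V


def logrank_test(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> TestResult:
    """k-group log-rank test; chi-square with k-1 df."""
    return stratified_logrank(time, event, group, np.zeros(len(time), dtype=int))


def stratified_logrank(
    time: np.ndarray, event: np.ndarray, group: np.ndarray, strata: np.ndarray
) -> TestResult:
    """Log-rank test with within-stratum O-E and variances summed across
    strata; with a single stratum this is exactly the plain test."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    strata = np.asarray(strata)
    if (time < 0).any():
        raise ValueError("survival times must be non-negative")
    groups = np.unique(group)
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if event.sum() == 0:
        raise ValueError("log-rank test undefined with no events")
    gidx = np.searchsorted(groups, group)
    z = np.zeros(k)
    V = np.zeros((k, k))
    for s in np.unique(strata):
        m = strata == s
        if len(np.unique(group[m])) < 2:
            warnings.warn(f"stratum {s!r} has a single group; contributes nothing")
            continue
        zs, Vs = _logrank_components(time[m], event[m], gidx[m], k)
        z += zs
        V += Vs
    z1, V1 = z[:-1], V[:-1, :-1]
    chi2 = float(z1 @ np.linalg.pinv(V1) @ z1)
    df = k - 1
    return TestResult(chi2, df, float(sps.chi2.sf(chi2, df)))


def kruskal_wallis(values: np.ndarray, group: np.ndarray) -> TestResult:
    """Rank-based H with tie correction; identical values give H=0, p=1."""
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    groups = np.unique(group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[group == g] for g in groups]
    if len(np.unique(values)) < 2:
        return TestResult(0.0, len(groups) - 1, 1.0)
    h, p = sps.kruskal(*samples)
    return TestResult(float(h), len(groups) - 1, float(p))


def signature_permutation_test(
    weights: pd.DataFrame,
    labels: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Per-signature permutation p-values for |mean(A) - mean(B)|.

    p = (1 + #{permutations with statistic >= observed}) / (n_perm + 1),
    so p is never exactly 0 and is bounded below by 1/(n_perm+1).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    cats = np.unique(labels)
    if len(cats) != 2:
        raise ValueError("labels must contain exactly 2 classes")
    W = weights.to_numpy(dtype=float)
    mask = labels == cats[0]
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("both labels must be present")

    def stat(m: np.ndarray) -> np.ndarray:
        return np.abs(W[m].mean(axis=0) - W[~m].mean(axis=0))

    obs = stat(mask)
    count = np.zeros(W.shape[1], dtype=int)
    for _ in range(n_perm):
        count += stat(rng.permutation(mask)) >= obs
    p = (1 + count) / (n_perm + 1)
    return pd.Series(p, index=weights.columns, name="p_value")


def km_median(time: np.ndarray, event: np.ndarray) -> float:
    """Kaplan-Meier median survival time (inf if the curve stays above 1/2)."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter().fit(time, event)
    return float(km.median_survival_time_)
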