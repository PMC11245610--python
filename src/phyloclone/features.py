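"""Tree-shape features: entropies of clone proportions and mutation loads.

Let Q = (q_1..q_S) be the subclone proportions and M = (m_1..m_S) the
unique-mutation counts rescaled to sum to 1. The proportion entropy
PE = -sum q_s log q_s and mutation entropy ME = -sum m_s log m_s (natural
log) measure the balance of cell mass and of mutation load across clones.
Seven derived features re-apply the Shannon entropy to renormalized
transforms of Q and M (component-wise ratio and product; squared and cubed
entries) plus the Pearson correlation of Q and M. Each entropy feature can
be normalized by log S, its maximum at S clones. The intratumor
heterogeneity (ITH) score is the product ME * PE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import ClonalTree

FEATURE_ORDER = (
    "PE", "ME", "cor", "E_ratio", "E_product",
    "ME_square", "ME_cube", "PE_square", "PE_cube",
)


def shannon_entropy(v: np.ndarray) -> float:
    """Shannon entropy (natural log) of a probability vector; 0*log 0 = 0."""
    v = np.asarray(v, dtype=float)
    if (v < 0).any():
        raise ValueError("probability vector has a negative entry")
    if abs(v.sum() - 1.0) > 1e-9:
        raise ValueError(f"probability vector must sum to 1, got {v.sum()!r}")
    nz = v[v > 0]
    return float(-(nz * np.log(nz)).sum())


def proportion_entropy(Q: np.ndarray) -> float:
    return shannon_entropy(Q)


def mutation_entropy(M: np.ndarray) -> float:
    return shannon_entropy(M)


def mutation_frequencies(tree: ClonalTree, pseudo_count: float = 0.5) -> np.ndarray:
    """Per-clone unique-mutation counts rescaled to sum to 1.

    Zero-count clones cannot arise from the in-package inference (they are
    pruned); for externally supplied trees a pseudo-count is injected with
    a warning so downstream ratios stay finite.
    """
    counts = np.asarray(tree.mut_counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("tree has no mutations")
    if (counts == 0).any():
        warnings.warn("zero-mutation clone in external tree; injecting pseudo-count")
        counts = counts + pseudo_count * (counts == 0)
    return counts / counts.sum()


def _renorm_entropy(v: np.ndarray) -> float:
    v = np.asarray(v, dtype=float)
    return shannon_entropy(v / v.sum())


def pearson_cor(Q: np.ndarray, M: np.ndarray, literal: bool = False) -> float:
    """Correlation of Q and M; zero variance in either vector gives 0.

    ``literal=True`` uses the single-square-root denominator
    sqrt(sum (q_i - qbar)^2 (m_i - mbar)^2) instead of the usual product of
    root-sums.
    """
    Q = np.asarray(Q, dtype=float)
    M = np.asarray(M, dtype=float)
    dq, dm = Q - Q.mean(), M - M.mean()
    if literal:
        den = np.sqrt((dq**2 * dm**2).sum())
    else:
        den = np.sqrt((dq**2).sum() * (dm**2).sum())
    if den < 1e-12:
        return 0.0
    r = float((dq * dm).sum() / den)
    # the literal single-root denominator is not variance-normalized and
    # may legitimately leave [-1, 1]
    return r if literal else float(np.clip(r, -1.0, 1.0))


@dataclass
class TreeFeatures:
    PE: float
    ME: float
    cor: float
    E_ratio: float
    E_product: float
    ME_square: float
    ME_cube: float
    PE_square: float
    PE_cube: float
    S: int
    normalized: bool

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_ORDER])


def feature_vector(
    tree: ClonalTree,
    normalized: bool = True,
    literal_cor: bool = False,
) -> TreeFeatures:
    """The nine shape features of one tree.

    When ``normalized``, each entropy feature is divided by log S (the
    correlation is never normalized); a single-clone tree has all entropies
    0 by convention.
    """
    Q = np.asarray(tree.q, dtype=float)
    M = mutation_frequencies(tree)
    S = tree.S
    raw = {
        "PE": shannon_entropy(Q),
        "ME": shannon_entropy(M),
        "E_ratio": _renorm_entropy(Q / M),
        "E_product": _renorm_entropy(Q * M),
        "ME_square": _renorm_entropy(M**2),
        "ME_cube": _renorm_entropy(M**3),
        "PE_square": _renorm_entropy(Q**2),
        "PE_cube": _renorm_entropy(Q**3),
    }
    if normalized:
        scale = np.log(S) if S > 1 else 1.0
        raw = {k: v / scale for k, v in raw.items()}
    return TreeFeatures(
        cor=pearson_cor(Q, M, literal=literal_cor),
        S=S,
        normalized=normalized,
        **raw,
    )


def ith_score(tree: ClonalTree, normalized: bool = False) -> float:
    """Intratumor heterogeneity: ME * PE (unnormalized by default, matching
    the scale on which single-tree values above 1 are reported)."""
    fv = feature_vector(tree, normalized=normalized)
    return fv.ME * fv.PE


def features_frame(trees: list[ClonalTree], normalized: bool = True) -> pd.DataFrame:
    """One row of features per tree, indexed by sample id, with the fixed
    column order used across the package."""
    rows = []
    for t in trees:
        fv = feature_vector(t, normalized=normalized)
        rows.append(
            {"sample_id": t.sample_id, **{f: getattr(fv, f) for f in FEATURE_ORDER},
             "S": fv.S, "normalized": fv.normalized}
        )
    return pd.DataFrame(rows).set_index("sample_id")
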