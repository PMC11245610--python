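"""Founding-clone driver profiling and the exact r x c association test.

A mutated gene is a potential driver of a tumor's evolution model when it
sits in the founding clone (the root of the clonal tree). Per-gene status
(no mutation / driver / not driver) is cross-tabulated against the
phylogeny class (linear / shallow / deep) and tested with the
Freeman-Halton extension of Fisher's exact test: the exact conditional
p-value sums the hypergeometric probabilities of every table with the
observed margins whose probability does not exceed the observed table's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .simulate import MutationCall
from .trees import ClonalTree

STATUS_ORDER = ("no mutation", "driver", "not driver")
CLASS_ORDER = ("linear", "shallow", "deep")

ENUMERATION_CAP = 200


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]


def founding_clone_genes(tree: ClonalTree, calls: list[MutationCall]) -> set[str]:
    """Genes of the mutations assigned to the root node."""
    if tree.assignment is None:
        assign = np.array([c.clone_index for c in calls])
    else:
        assign = np.asarray(tree.assignment)
    if len(assign) != len(calls):
        raise ValueError("tree assignment does not cover the calls")
    genes = {calls[i].gene for i in np.flatnonzero(assign == 0)}
    if not genes:
        warnings.warn(f"empty founding clone for sample {tree.sample_id}")
    return genes


def gene_status(tree: ClonalTree, calls: list[MutationCall], gene: str) -> str:
    """'no mutation' if absent, 'driver' if in the founding clone,
    'not driver' if present only in subclones."""
    present = any(c.gene == gene for c in calls)
    if not present:
        return "no mutation"
    root = founding_clone_genes(tree, calls) if calls else set()
    return "driver" if gene in root else "not driver"


def driver_status_table(
    statuses: dict[str, str], labels: dict[str, str]
) -> ContingencyTable:
    """3x3 counts of gene status by phylogeny class; samples with labels
    outside {linear, shallow, deep} are excluded (logged)."""
    counts = np.zeros((3, 3), dtype=int)
    excluded = 0
    for sid, status in statuses.items():
        lab = labels.get(sid)
        if lab not in CLASS_ORDER:
            excluded += 1
            continue
        counts[STATUS_ORDER.index(status), CLASS_ORDER.index(lab)] += 1
    if excluded:
        warnings.warn(f"excluded {excluded} samples with unresolved labels")
    return ContingencyTable(counts, STATUS_ORDER, CLASS_ORDER)


def _log_table_prob(counts: np.ndarray, lognum: float) -> float:
    return lognum - gammaln(counts + 1).sum()


def freeman_halton_test(
    table: ContingencyTable | np.ndarray,
    tie_tol: float = 1e-7,
    monte_carlo: bool = False,
    n_samples: int = 100_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Exact conditional p-value for an r x c table with fixed margins.

    Enumerates all margin-compatible tables depth-first in log space; the
    p-value sums the probabilities of tables whose log-probability is at
    most the observed one plus ``tie_tol`` (stabilizing floating-point
    ties). Tables with grand total above 200 must use ``monte_carlo``.
    """
    counts = np.asarray(table.counts if isinstance(table, ContingencyTable) else table,
                        dtype=int)
    if (counts < 0).any() or counts.sum() == 0:
        raise ValueError("table must be non-negative with a positive total")
    # degenerate margins carry no information
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        return 1.0
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    n = counts.sum()
    lognum = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)
    logp_obs = _log_table_prob(counts, lognum)

    if monte_carlo:
        return _fh_monte_carlo(rows, cols, lognum, logp_obs, tie_tol, n_samples, rng)
    if n > ENUMERATION_CAP:
        raise ValueError(
            f"grand total {n} exceeds the enumeration cap {ENUMERATION_CAP}; "
            "use monte_carlo=True"
        )

    r, c = counts.shape
    logfact = gammaln(np.arange(n + 1) + 1.0)
    target = logp_obs + tie_tol
    logps: list[float] = []

    def fill_row(i: int, col_rem: np.ndarray, acc: float) -> None:
        if i == r - 1:  # last row forced by column margins
            logps_val = acc - logfact[col_rem].sum()
            if logps_val <= target:
                logps.append(logps_val)
            return

        row_total = rows[i]

        def fill_cell(j: int, rem: int, col_rem: np.ndarray, acc2: float) -> None:
            if j == c - 1:
                if rem <= col_rem[j]:
                    nxt = col_rem.copy()
                    nxt[j] -= rem
                    fill_row(i + 1, nxt, acc2 - logfact[rem])
                return
            hi = min(rem, col_rem[j])
            # remaining cells in this row must be able to absorb the rest
            lo = max(0, rem - int(col_rem[j + 1 :].sum()))
            for v in range(lo, hi + 1):
                nxt = col_rem.copy()
                nxt[j] -= v
                fill_cell(j + 1, rem - v, nxt, acc2 - logfact[v])

        fill_cell(0, row_total, col_rem, acc)

    fill_row(0, cols.copy(), lognum)
    if not logps:
        return 1.0
    m = max(logps)
    p = float(np.exp(m) * np.exp(np.asarray(logps) - m).sum())
    return min(p, 1.0)


def _fh_monte_carlo(rows, cols, lognum, logp_obs, tie_tol, n_samples, rng) -> float:
    """Seeded Monte-Carlo estimate: random tables with the observed margins
    via random permutation, add-one p-value."""
    if rng is None:
        rng = np.random.default_rng(0)
    row_ids = np.repeat(np.arange(len(rows)), rows)
    col_ids = np.repeat(np.arange(len(cols)), cols)
    hits = 0
    for _ in range(n_samples):
        perm = rng.permutation(col_ids)
        t = np.zeros((len(rows), len(cols)), dtype=int)
        np.add.at(t, (row_ids, perm), 1)
        if _log_table_prob(t, lognum) <= logp_obs + tie_tol:
            hits += 1
    return (hits + 1) / (n_samples + 1)


def phylogeny_mutation_summary(
    founding_sets: dict[str, set[str]], labels: dict[str, str]
) -> pd.DataFrame:
    """Per class, genes ranked by the fraction of samples carrying a
    founding-clone mutation in them (ties alphabetical)."""
    rows = []
    for cls in CLASS_ORDER:
        sids = [s for s, l in labels.items() if l == cls]
        n_cls = len(sids)
        freq: dict[str, int] = {}
        for s in sids:
            for g in founding_sets.get(s, set()):
                freq[g] = freq.get(g, 0) + 1
        ranked = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
        for rank, (g, k) in enumerate(ranked, start=1):
            rows.append(
                {"class": cls, "rank": rank, "gene": g,
                 "frequency": k / n_cls if n_cls else 0.0, "n_class": n_cls}
            )
    return pd.DataFrame(rows, columns=["class", "rank", "gene", "frequency", "n_class"])
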