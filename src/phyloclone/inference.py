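"""Maximum-likelihood clonal-tree reconstruction from read counts.

For every rooted tree shape on 1-5 nodes, alt-read counts are modeled as a
mixture of binomials whose success probabilities come from the cellular
prevalences ``phi`` of the clones (VAF = purity * phi / 2 under the default
diploid, multiplicity-1 model). An EM algorithm fits each topology under
the subtree constraint phi(parent) >= sum of children's phi; the tree is
then selected by BIC.

Topology identifiability caveat: with single-sample diploid data any
branching prevalence set is also exactly representable as a chain, so the
likelihood ties between the two. Ties are resolved by preferring the
topology whose implied clone proportions maximize the smallest clone — a
balanced branching pair read as a chain would imply an implausibly small
intermediate clone — and, on exact ties, the less-branched shape. Skewed
(shallow-type) branching is genuinely confounded with chains in this
regime; see the methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .simulate import MutationCall
from .trees import ClonalTree, Topology, enumerate_topologies, write_newick  # noqa: F401

_PHI_MIN = 1e-4
_P_EPS = 1e-9


@dataclass
class EMResult:
    phi: np.ndarray
    pi: np.ndarray
    resp: np.ndarray  # n_mutations x k posterior over nodes
    assignment: np.ndarray  # hard assignment by maximum posterior
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True


def _extract_counts(
    calls, purity: float, include_cn: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(alt, tot, denom, kept_index); denom is the per-call VAF denominator
    purity*C_T + 2(1-purity). Non-diploid loci are dropped unless
    ``include_cn`` switches to the general copy-number formula."""
    alt, tot, denom, kept = [], [], [], []
    for i, c in enumerate(calls):
        if isinstance(c, MutationCall):
            a, t, cn = c.alt_reads, c.total_reads, c.major_cn + c.minor_cn
        else:  # (alt, total) pair
            a, t, cn = int(c[0]), int(c[1]), 2
        if cn != 2 and not include_cn:
            continue
        alt.append(a)
        tot.append(t)
        denom.append(purity * cn + 2.0 * (1.0 - purity))
        kept.append(i)
    return (
        np.asarray(alt, dtype=float),
        np.asarray(tot, dtype=float),
        np.asarray(denom, dtype=float),
        np.asarray(kept, dtype=int),
    )


def _project_subtree_constraint(phi: np.ndarray, parent: np.ndarray) -> np.ndarray:
    """Scale subtrees so every node satisfies sum(children phi) <= own phi
    and the root stays <= 1 (iterative clipping, preserving ratios within
    each offending sibling set)."""
    phi = np.minimum(phi, 1.0).copy()
    k = len(parent)
    ch: list[list[int]] = [[] for _ in range(k)]
    for i in range(1, k):
        ch[parent[i]].append(i)

    def scale(v: int, f: float) -> None:
        phi[v] *= f
        for c in ch[v]:
            scale(c, f)

    for v in range(k):  # parents precede children
        s = sum(phi[c] for c in ch[v])
        if s > phi[v]:
            f = phi[v] / s
            for c in ch[v]:
                scale(c, f)
    return np.maximum(phi, _PHI_MIN)


def binomial_mixture_em(
    calls,
    topology: Topology | np.ndarray,
    purity: float,
    phi_init: np.ndarray | None = None,
    pi_init: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    include_cn: bool = False,
) -> EMResult:
    """Fit the constrained binomial mixture for one topology.

    The log-likelihood trace is non-decreasing: if the constraint
    projection ever lowers it, the previous iterate is kept and the fit
    stops (flagged converged).
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    parent = np.asarray(topology.parent if isinstance(topology, Topology) else topology)
    k = len(parent)
    alt, tot, denom, _ = _extract_counts(calls, purity, include_cn)
    n = len(alt)
    if n == 0:
        raise ValueError("no usable mutation calls")

    logc = gammaln(tot + 1) - gammaln(alt + 1) - gammaln(tot - alt + 1)

    def comp_loglik(phi: np.ndarray, pi: np.ndarray) -> tuple[np.ndarray, float]:
        p = np.clip(purity * phi[None, :] / denom[:, None], _P_EPS, 1 - _P_EPS)
        lc = logc[:, None] + alt[:, None] * np.log(p) + (tot - alt)[:, None] * np.log1p(-p)
        lj = lc + np.log(pi)[None, :]
        ll = logsumexp(lj, axis=1)
        return lj - ll[:, None], float(ll.sum())

    if phi_init is None:
        base = np.quantile(np.clip(alt / tot * denom / purity, 1e-3, 1.0),
                           1 - (np.arange(k) + 0.5) / k)  # descending
        phi = np.empty(k)
        phi[_node_order(parent)] = base  # root gets the largest prevalence
        phi = _project_subtree_constraint(phi, parent)
    else:
        phi = _project_subtree_constraint(np.asarray(phi_init, dtype=float), parent)
    pi = np.full(k, 1.0 / k) if pi_init is None else np.asarray(pi_init, dtype=float)

    log_resp, ll = comp_loglik(phi, pi)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gamma = np.exp(log_resp)
        pi_new = np.clip(gamma.mean(axis=0), 1e-12, None)
        pi_new /= pi_new.sum()
        num = gamma.T @ (alt * denom)  # fold denom back so phi is on the cell scale
        den = gamma.T @ (tot * purity)
        phi_new = np.clip(np.where(den > 0, num / np.maximum(den, 1e-300), phi), _PHI_MIN, 1.0)
        phi_new = _project_subtree_constraint(phi_new, parent)
        log_resp_new, ll_new = comp_loglik(phi_new, pi_new)
        if ll_new < trace[-1] - 1e-9:
            # constraint projection moved downhill; keep the previous iterate
            converged = True
            break
        phi, pi, log_resp = phi_new, pi_new, log_resp_new
        trace.append(ll_new)
        if abs(ll_new - trace[-2]) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("EM reached max_iter without converging; returning best iterate")
    resp = np.exp(log_resp)
    return EMResult(
        phi=phi,
        pi=pi,
        resp=resp,
        assignment=np.argmax(resp, axis=1),
        loglik=trace[-1],
        loglik_trace=trace,
        n_iter=it,
        converged=converged,
    )


def _node_order(parent: np.ndarray) -> np.ndarray:
    """Rank of each node by (depth, index): the root gets the largest
    initial prevalence, deeper nodes smaller ones."""
    depth = np.zeros(len(parent), dtype=int)
    for i in range(1, len(parent)):
        depth[i] = depth[parent[i]] + 1
    return np.lexsort((np.arange(len(parent)), depth))


def implied_proportions(phi: np.ndarray, parent: np.ndarray) -> np.ndarray:
    """q(node) = phi(node) - sum of children's phi, renormalized."""
    q = phi.astype(float).copy()
    for i in range(1, len(parent)):
        q[parent[i]] -= phi[i]
    q = np.clip(q, 0.0, None)
    s = q.sum()
    return q / s if s > 0 else np.full_like(q, 1.0 / len(q))


def classify_linearity(tree: ClonalTree) -> str:
    """'linear' iff every node has at most one child."""
    return "linear" if tree.is_linear else "nonlinear"


def select_tree(
    calls,
    purity: float,
    k_max: int = 5,
    restarts: int = 10,
    rng: np.random.Generator | None = None,
    criterion: str = "bic",
    include_cn: bool = False,
    tol: float = 1e-6,
    max_iter: int = 500,
    tie_loglik: float = 0.5,
    sample_id: str = "sample",
) -> ClonalTree:
    """Fit every topology with 1..k_max nodes and return the selected tree.

    Selection is by BIC (default; ``criterion='ml'`` uses raw likelihood,
    which is non-decreasing in the clone count). Fits within ``tie_loglik``
    of the winner are tied; ties go to the topology maximizing the minimum
    implied clone proportion, then to the one with fewer leaves.
    """
    if len(calls) == 0:
        raise ValueError("calls must be non-empty")
    if rng is None:
        rng = np.random.default_rng(0)
    alt, tot, denom, _ = _extract_counts(calls, purity, include_cn)
    n = len(alt)
    if n == 0:
        warnings.warn("no diploid calls usable; falling back to a single-clone tree")
        return ClonalTree(sample_id, [-1], [1.0], [max(1, len(calls))], loglik=float("nan"))
    phi_obs = np.clip(alt / np.maximum(tot, 1) * denom / purity, 1e-3, 1.0)

    fits: list[tuple[Topology, EMResult]] = []
    for topo in enumerate_topologies(k_max):
        k = topo.k
        parent = np.asarray(topo.parent)
        base = np.quantile(phi_obs, 1 - (np.arange(k) + 0.5) / k)  # descending
        order = _node_order(parent)
        best: EMResult | None = None
        for r in range(max(1, restarts)):
            init = base.copy()
            if r > 0:
                init = np.clip(init * np.exp(rng.normal(0.0, 0.15, size=k)), 1e-3, 1.0)
                init = np.sort(init)[::-1]
            phi0 = np.empty(k)
            phi0[order] = init
            try:
                res = binomial_mixture_em(
                    calls, topo, purity, phi_init=phi0,
                    tol=tol, max_iter=max_iter, include_cn=include_cn,
                )
            except (ValueError, FloatingPointError):
                continue
            if best is None or res.loglik > best.loglik:
                best = res
        if best is not None:
            fits.append((topo, best))
    if not fits:
        warnings.warn("all topology fits degenerate; falling back to single clone")
        return ClonalTree(sample_id, [-1], [1.0], [n], loglik=float("nan"))

    def score(item: tuple[Topology, EMResult]) -> float:
        topo, res = item
        if criterion == "ml":
            return -res.loglik
        return -2.0 * res.loglik + (2 * topo.k - 1) * np.log(n)

    best_score = min(score(f) for f in fits)
    tied = [f for f in fits if score(f) <= best_score + 2.0 * tie_loglik]
    # maximize the smallest implied clone; differences below min_q_margin are
    # not treated as evidence, in which case the less-branched shape wins
    min_q_margin = 0.03
    minqs = [implied_proportions(r.phi, np.asarray(t.parent)).min() for t, r in tied]
    best_minq = max(minqs)
    finalists = [f for f, mq in zip(tied, minqs) if mq >= best_minq - min_q_margin]
    finalists.sort(key=lambda f: (f[0].n_leaves, f[0].canonical_key))
    topo, res = finalists[0]
    return _build_tree(sample_id, topo, res)


def _build_tree(sample_id: str, topo: Topology, res: EMResult) -> ClonalTree:
    """Hard-assign mutations, prune zero-mutation clones, renormalize q."""
    parent = list(topo.parent)
    phi = res.phi.copy()
    assign = res.assignment.copy()
    counts = np.bincount(assign, minlength=len(parent))

    nodes = list(range(len(parent)))
    while len(nodes) > 1:
        empty = [v for v in nodes if counts[v] == 0 and v != nodes[0]]
        if not empty:
            break
        v = empty[-1]
        for i in nodes:
            if i != v and parent[i] == v:
                parent[i] = parent[v]
        nodes.remove(v)

    remap = {v: j for j, v in enumerate(nodes)}
    new_parent = np.array([-1] + [remap[parent[v]] for v in nodes[1:]])
    q = implied_proportions(phi, np.asarray(topo.parent))
    q = np.array([q[v] for v in nodes])
    q = np.maximum(q, 1e-6)
    q /= q.sum()
    new_assign = np.array([remap[a] for a in assign]) if len(nodes) < len(parent) else assign
    new_counts = np.bincount(new_assign, minlength=len(nodes))
    return ClonalTree(
        sample_id=sample_id,
        parent=new_parent,
        q=q,
        mut_counts=new_counts,
        assignment=new_assign,
        loglik=res.loglik,
        converged=res.converged,
        meta={"loglik_trace": res.loglik_trace},
    )
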