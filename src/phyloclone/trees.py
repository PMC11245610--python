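"""Rooted clonal trees of tumor subclones.

A clonal tree has the founding clone F at the root; every node carries a
proportion ``q`` (fraction of tumor cells belonging to exactly that clone)
and a count of unique somatic mutations. The cellular prevalence ``phi`` of
a clone is the fraction of tumor cells carrying its mutations, i.e. the sum
of ``q`` over the clone and all of its descendants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MAX_SUBCLONES = 5


@dataclass
class Topology:
    """A rooted tree shape on ``k`` nodes, as a parent vector.

    Node 0 is the root; ``parent[i] < i`` for i > 0 so the vector is a
    topological order. ``canonical_key`` is the AHU canonical string, unique
    per unlabeled rooted shape.
    """

    parent: tuple[int, ...]
    canonical_key: str

    @property
    def k(self) -> int:
        return len(self.parent)

    @property
    def is_chain(self) -> bool:
        counts = np.zeros(self.k, dtype=int)
        for p in self.parent[1:]:
            counts[p] += 1
        return bool((counts <= 1).all())

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.k)]
        for i, p in enumerate(self.parent[1:], start=1):
            ch[p].append(i)
        return ch

    @property
    def n_leaves(self) -> int:
        return sum(1 for c in self.children() if not c)


def _ahu_key(parent: tuple[int, ...]) -> str:
    """AHU canonical form: sorted parenthesization of subtrees."""
    ch: list[list[int]] = [[] for _ in parent]
    for i, p in enumerate(parent[1:], start=1):
        ch[p].append(i)

    def enc(v: int) -> str:
        return "(" + "".join(sorted(enc(c) for c in ch[v])) + ")"

    return enc(0)


def enumerate_topologies(k_max: int = MAX_SUBCLONES) -> list[Topology]:
    """All unlabeled rooted tree shapes with 1..k_max nodes.

    Shapes are deduplicated by AHU canonical form; counts follow the rooted
    unlabeled tree numbers 1, 1, 2, 4, 9 for k = 1..5.
    """
    if not 1 <= k_max <= MAX_SUBCLONES:
        raise ValueError(f"k_max must be in [1, {MAX_SUBCLONES}], got {k_max}")
    out: list[Topology] = []
    for k in range(1, k_max + 1):
        seen: dict[str, tuple[int, ...]] = {}
        # parent[i] in {0..i-1} covers every shape at least once
        def rec(par: list[int]) -> None:
            i = len(par)
            if i == k:
                tup = tuple(par)
                key = _ahu_key(tup)
                seen.setdefault(key, tup)
                return
            for p in range(i):
                rec(par + [p])

        rec([-1])
        for key in sorted(seen):
            out.append(Topology(parent=seen[key], canonical_key=key))
    return out


@dataclass
class ClonalTree:
    """A fitted or simulated clonal tree for one tumor sample."""

    sample_id: str
    parent: np.ndarray  # parent[0] == -1 (founding clone F)
    q: np.ndarray  # clone proportions, sum to 1
    mut_counts: np.ndarray  # unique mutations per clone
    assignment: np.ndarray | None = None  # mutation index -> node
    loglik: float = float("nan")
    converged: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.q = np.asarray(self.q, dtype=float)
        self.mut_counts = np.asarray(self.mut_counts, dtype=int)
        if self.parent[0] != -1:
            raise ValueError("node 0 must be the root (parent -1)")
        if not (1 <= self.S <= MAX_SUBCLONES):
            raise ValueError(f"tree must have 1..{MAX_SUBCLONES} nodes, got {self.S}")
        if abs(self.q.sum() - 1.0) > 1e-9:
            raise ValueError(f"clone proportions must sum to 1, got {self.q.sum()!r}")
        if (self.q <= 0).any():
            raise ValueError("all clone proportions must be positive")

    @property
    def S(self) -> int:
        return len(self.parent)

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.S)]
        for i, p in enumerate(self.parent[1:], start=1):
            ch[p].append(i)
        return ch

    @property
    def is_linear(self) -> bool:
        return all(len(c) <= 1 for c in self.children())

    def prevalence(self) -> np.ndarray:
        """phi per node: sum of q over the node and its descendants."""
        phi = self.q.copy()
        # parent[i] < i, so a reverse sweep accumulates subtrees
        for i in range(self.S - 1, 0, -1):
            phi[self.parent[i]] += phi[i]
        return phi

    def node_name(self, i: int) -> str:
        return "F" if i == 0 else str(i)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "parent": self.parent.tolist(),
            "q": self.q.tolist(),
            "mut_counts": self.mut_counts.tolist(),
            "assignment": None if self.assignment is None else np.asarray(self.assignment).tolist(),
            "loglik": self.loglik,
            "linear": self.is_linear,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClonalTree":
        return cls(
            sample_id=d["sample_id"],
            parent=np.asarray(d["parent"]),
            q=np.asarray(d["q"], dtype=float),
            mut_counts=np.asarray(d["mut_counts"]),
            assignment=None if d.get("assignment") is None else np.asarray(d["assignment"]),
            loglik=d.get("loglik", float("nan")),
        )


def write_newick(tree: ClonalTree) -> str:
    """Serialize with branch length = the clone's unique-mutation count.

    The root's count is carried as the root branch length, e.g. a chain
    F->1->2 with counts (2, 5, 3) becomes ``((2:3)1:5)F:2;``.
    """
    ch = tree.children()

    def enc(v: int) -> str:
        inner = "" if not ch[v] else "(" + ",".join(enc(c) for c in ch[v]) + ")"
        return f"{inner}{tree.node_name(v)}:{tree.mut_counts[v]}"

    return enc(0) + ";"
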