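"""Synthetic tumor cohorts with known ground truth.

Generates clonal trees per phylogeny class (linear / shallow branching /
deep branching), binomial read counts under the cellular-prevalence model,
exponential survival with class-dependent hazards, Dirichlet immune-cell
fractions with a B-cell enrichment in linear tumors, Dirichlet mutational
signature weights, and founding-clone driver-gene placement.

Every stage draws from a named substream spawned from one master seed, so a
cohort is bit-reproducible and stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .trees import ClonalTree, enumerate_topologies

LABELS = ("linear", "shallow", "deep")

#: LM22-style reference immune cell types (22 of them); the three B-lineage
#: types receive the linear-class concentration shift.
CELL_TYPES = (
    "B cells naive",
    "B cells memory",
    "Plasma cells",
    "T cells CD8",
    "T cells CD4 naive",
    "T cells CD4 memory resting",
    "T cells CD4 memory activated",
    "T cells follicular helper",
    "T cells regulatory",
    "T cells gamma delta",
    "NK cells resting",
    "NK cells activated",
    "Monocytes",
    "Macrophages M0",
    "Macrophages M1",
    "Macrophages M2",
    "Dendritic cells resting",
    "Dendritic cells activated",
    "Mast cells resting",
    "Mast cells activated",
    "Eosinophils",
    "Neutrophils",
)
B_CELL_TYPES = ("B cells naive", "B cells memory", "Plasma cells")

#: Synthetic signature catalogue (names follow the SBS convention; the
#: spectra themselves are not modeled).
SIGNATURES = tuple(
    f"SBS{i}" for i in (1, 4, 5, 6, 12, 15, 16, 18, 22, 24, 29, 35, 40, 44)
)

LINEAR_DRIVER = "GTF2IRD2B"
NONLINEAR_DRIVER = "TP53"

DEFAULT_DRIVER_ENRICHMENT = {
    LINEAR_DRIVER: {"linear": 0.9, "shallow": 0.05, "deep": 0.05},
    NONLINEAR_DRIVER: {"linear": 0.1, "shallow": 0.8, "deep": 0.8},
}


@dataclass
class MutationCall:
    """One somatic SNV with read support and copy-number context."""

    sample_id: str
    gene: str
    chrom: str
    pos: int  # 1-based
    alt_reads: int
    total_reads: int
    major_cn: int = 1
    minor_cn: int = 1
    clone_index: int | None = None  # ground truth; 0 = founding clone

    def __post_init__(self) -> None:
        if self.alt_reads < 0 or self.total_reads < 1:
            raise ValueError("need alt_reads >= 0 and total_reads >= 1")
        if self.alt_reads > self.total_reads:
            raise ValueError(
                f"alt_reads ({self.alt_reads}) exceeds total_reads ({self.total_reads})"
            )
        if self.minor_cn > self.major_cn:
            raise ValueError("minor_cn must not exceed major_cn")


@dataclass
class TumorSample:
    sample_id: str
    cohort: str = "SYNTH"
    purity: float = 1.0
    ploidy: float = 2.0
    calls: list[MutationCall] = field(default_factory=list)
    survival_time: float = 0.0
    event: int = 0
    stage: str | None = None
    immune_fractions: dict[str, float] | None = None
    signature_weights: dict[str, float] | None = None
    true_class: str | None = None
    true_tree: ClonalTree | None = None


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort; defaults are the conditions
    used throughout the package's experiments."""

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"linear": 50, "shallow": 50, "deep": 50}
    )
    depth_mean: float = 150.0
    purity_range: tuple[float, float] = (0.5, 0.9)
    subclone_range: tuple[int, int] = (1, 5)
    balance_alpha: dict[str, float] = field(
        default_factory=lambda: {"linear": 5.0, "shallow": 0.3, "deep": 50.0}
    )
    mean_mutations: dict[str, float] = field(
        default_factory=lambda: {"linear": 12.0, "shallow": 25.0, "deep": 25.0}
    )
    class_hazards: dict[str, float] = field(
        default_factory=lambda: {"linear": 0.02, "shallow": 0.04, "deep": 0.08}
    )
    t_max: float = 120.0  # months; administrative censoring horizon
    bcell_shift: float = 1.0
    sig_shift: float = 1.0
    driver_enrichment: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(d) for g, d in DEFAULT_DRIVER_ENRICHMENT.items()}
    )
    master_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.subclone_range
        if not (1 <= lo <= hi <= 5):
            raise ValueError("subclone_range must lie within [1, 5]")
        if any(h <= 0 for h in self.class_hazards.values()):
            raise ValueError("class hazards must be positive")


def _substream(master_seed: int, name: str) -> np.random.Generator:
    """Named, reproducible substream of the master seed."""
    order = ("trees", "reads", "clinical", "immune", "signatures", "drivers", "misc")
    return np.random.default_rng(np.random.SeedSequence((master_seed, order.index(name))))


# ---------------------------------------------------------------------------
# trees


def simulate_tree(
    label: str,
    n_subclones: int,
    rng: np.random.Generator,
    balance_alpha: float | None = None,
    mean_mutations: float | None = None,
    sample_id: str = "SYNTH",
) -> ClonalTree:
    """Draw one ground-truth clonal tree of the given phylogeny class.

    ``n_subclones`` counts the founding clone among the nodes. Linear trees
    are chains with proportions sorted so the founding clone dominates;
    branching trees use a random non-chain shape with proportions and
    mutation counts drawn from a Dirichlet whose concentration controls
    balance (high = deep branching, low = shallow branching).
    """
    if label not in LABELS:
        raise ValueError(f"unknown phylogeny label {label!r}")
    if not 1 <= n_subclones <= 5:
        raise ValueError("n_subclones must be in [1, 5]")
    if label != "linear" and n_subclones < 3:
        raise ValueError("branching trees need at least 3 nodes")
    defaults = {"linear": 5.0, "shallow": 0.3, "deep": 50.0}
    alpha = defaults[label] if balance_alpha is None else float(balance_alpha)
    mean_mut = {"linear": 12.0, "shallow": 25.0, "deep": 25.0}[label] \
        if mean_mutations is None else float(mean_mutations)

    S = n_subclones
    if label == "linear":
        parent = np.arange(-1, S - 1)
    else:
        shapes = [t for t in enumerate_topologies(S) if t.k == S and not t.is_chain]
        parent = np.asarray(shapes[rng.integers(len(shapes))].parent)

    q = rng.dirichlet(np.full(S, alpha))
    q = np.maximum(q, 1e-6)
    q /= q.sum()
    if label == "linear":
        q = np.sort(q)[::-1]  # dominant founding clone, shrinking along the chain

    total = max(S, int(rng.poisson(mean_mut)))
    w = rng.dirichlet(np.full(S, alpha))
    counts = rng.multinomial(total - S, w) + 1  # every clone keeps >= 1 mutation
    return ClonalTree(
        sample_id=sample_id,
        parent=parent,
        q=q,
        mut_counts=counts,
        meta={"true_class": label},
    )


# ---------------------------------------------------------------------------
# reads


def expected_vaf(
    phi: float | np.ndarray,
    purity: float,
    multiplicity: int = 1,
    tumor_cn: int = 2,
) -> float | np.ndarray:
    """Expected variant allele fraction of mutations at prevalence ``phi``.

    VAF = purity * m * phi / (purity * C_T + 2 * (1 - purity)); the default
    diploid, multiplicity-1 model reduces to purity * phi / 2.
    """
    return purity * multiplicity * phi / (purity * tumor_cn + 2.0 * (1.0 - purity))


def simulate_reads(
    tree: ClonalTree,
    purity: float,
    depth_mean: float,
    n_mutations: int | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str | None = None,
) -> list[MutationCall]:
    """Binomial read counts for every mutation of a tree.

    Mutations follow the tree's per-clone counts (or are split
    proportionally when ``n_mutations`` overrides the total); read depth is
    Poisson(depth_mean) truncated at 1 and alt reads are
    Binomial(depth, VAF(phi)).
    """
    if rng is None:
        raise ValueError("rng is required")
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    if (tree.q <= 0).any():
        raise ValueError("tree has a zero-proportion clone")
    counts = tree.mut_counts.copy()
    if n_mutations is not None:
        if n_mutations < tree.S:
            raise ValueError("need at least one mutation per clone")
        w = counts / counts.sum()
        counts = rng.multinomial(n_mutations - tree.S, w) + 1
    phi = tree.prevalence()
    sid = sample_id or tree.sample_id
    calls: list[MutationCall] = []
    idx = 0
    for node in range(tree.S):
        p = float(expected_vaf(phi[node], purity))
        for _ in range(int(counts[node])):
            depth = int(rng.poisson(depth_mean))
            while depth < 1:
                depth = int(rng.poisson(depth_mean))
            alt = int(rng.binomial(depth, p))
            idx += 1
            calls.append(
                MutationCall(
                    sample_id=sid,
                    gene=f"GENE{idx:04d}",
                    chrom=str(1 + (idx - 1) % 22),
                    pos=1000 * idx + 1,
                    alt_reads=alt,
                    total_reads=depth,
                    clone_index=node,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# clinical / immune / signatures / drivers


def simulate_clinical(
    label: str,
    class_hazards: dict[str, float],
    rng: np.random.Generator,
    t_max: float = 120.0,
    censor_rate: float | None = None,
) -> tuple[float, int]:
    """(survival_time, event) with exponential event times.

    Default censoring is an independent Uniform(0, t_max) administrative
    time. ``censor_rate`` instead censors each sample with that probability
    at a Uniform(0, T) time strictly before its event, which realizes the
    fully-censored (rate 1) and uncensored (rate 0) limits exactly.
    """
    h = class_hazards[label]
    if h <= 0:
        raise ValueError("hazard must be positive")
    t_event = rng.exponential(1.0 / h)
    if censor_rate is not None:
        if rng.random() < censor_rate:
            return float(rng.uniform(0.0, t_event)), 0
        return float(t_event), 1
    c = rng.uniform(0.0, t_max)
    if t_event <= c:
        return float(t_event), 1
    return float(c), 0


def simulate_immune(
    label: str,
    bcell_shift: float,
    rng: np.random.Generator,
    base_alpha: float = 1.0,
) -> dict[str, float]:
    """Dirichlet fractions over the 22 reference cell types; B-lineage
    concentrations are multiplied by (1 + bcell_shift) for linear tumors."""
    if bcell_shift < 0:
        raise ValueError("bcell_shift must be >= 0")
    alpha = np.full(len(CELL_TYPES), base_alpha)
    if label == "linear":
        for i, ct in enumerate(CELL_TYPES):
            if ct in B_CELL_TYPES:
                alpha[i] *= 1.0 + bcell_shift
    frac = rng.dirichlet(alpha)
    return dict(zip(CELL_TYPES, frac.tolist()))


def simulate_signatures(
    label: str,
    rng: np.random.Generator,
    sig_shift: float = 0.0,
    signatures: tuple[str, ...] = SIGNATURES,
    shifted_signature: str = "SBS15",
) -> dict[str, float]:
    """Dirichlet signature weights; one signature's concentration is
    up-weighted by (1 + sig_shift) in linear tumors (mismatch-repair-like
    enrichment)."""
    alpha = np.ones(len(signatures))
    if label == "linear" and sig_shift > 0:
        alpha[signatures.index(shifted_signature)] *= 1.0 + sig_shift
    w = rng.dirichlet(alpha)
    return dict(zip(signatures, w.tolist()))


def simulate_driver_genes(
    tree: ClonalTree,
    label: str,
    driver_enrichment: dict[str, dict[str, float]],
    rng: np.random.Generator,
    calls: list[MutationCall],
    subclonal_rate: float = 0.05,
) -> list[MutationCall]:
    """Relabel mutation genes in place: each configured driver gene is
    placed on a founding-clone mutation with its class-dependent
    probability; otherwise it may appear subclonally at a low background
    rate. Remaining mutations keep background gene names."""
    root_idx = [i for i, c in enumerate(calls) if c.clone_index == 0]
    sub_idx = [i for i, c in enumerate(calls) if c.clone_index not in (0, None)]
    taken: set[int] = set()
    for gene, probs in driver_enrichment.items():
        p = probs.get(label, 0.0)
        if not 0.0 <= p <= 1.0:
            raise ValueError("enrichment probabilities must be in [0, 1]")
        free = [i for i in root_idx if i not in taken]
        free_sub = [i for i in sub_idx if i not in taken]
        if free and rng.random() < p:
            i = int(free[rng.integers(len(free))])
            calls[i].gene = gene
            taken.add(i)
        elif free_sub and rng.random() < subclonal_rate:
            i = int(free_sub[rng.integers(len(free_sub))])
            calls[i].gene = gene
            taken.add(i)
    return calls


# ---------------------------------------------------------------------------
# cohort orchestration


def simulate_cohort(config: SimulationConfig | None = None, **overrides) -> list[TumorSample]:
    """Generate a full cohort under the configured study conditions."""
    if config is None:
        config = SimulationConfig()
    if overrides:
        config = dataclasses.replace(config, **overrides)
    rng_tree = _substream(config.master_seed, "trees")
    rng_reads = _substream(config.master_seed, "reads")
    rng_clin = _substream(config.master_seed, "clinical")
    rng_imm = _substream(config.master_seed, "immune")
    rng_sig = _substream(config.master_seed, "signatures")
    rng_drv = _substream(config.master_seed, "drivers")

    lo, hi = config.subclone_range
    samples: list[TumorSample] = []
    i = 0
    for label in LABELS:
        for _ in range(config.n_per_class.get(label, 0)):
            i += 1
            sid = f"SYN{i:04d}"
            s_lo = max(lo, 3) if label != "linear" else lo
            s_hi = max(hi, s_lo)
            S = int(rng_tree.integers(s_lo, s_hi + 1))
            tree = simulate_tree(
                label,
                S,
                rng_tree,
                balance_alpha=config.balance_alpha[label],
                mean_mutations=config.mean_mutations[label],
                sample_id=sid,
            )
            purity = float(rng_reads.uniform(*config.purity_range))
            calls = simulate_reads(tree, purity, config.depth_mean, rng=rng_reads)
            calls = simulate_driver_genes(
                tree, label, config.driver_enrichment, rng_drv, calls
            )
            time, event = simulate_clinical(
                label, config.class_hazards, rng_clin, t_max=config.t_max
            )
            samples.append(
                TumorSample(
                    sample_id=sid,
                    purity=purity,
                    calls=calls,
                    survival_time=time,
                    event=event,
                    immune_fractions=simulate_immune(label, config.bcell_shift, rng_imm),
                    signature_weights=simulate_signatures(
                        label, rng_sig, sig_shift=config.sig_shift
                    ),
                    true_class=label,
                    true_tree=tree,
                )
            )
    return samples


def recovery_panel(
    n: int,
    rng: np.random.Generator,
    depth_mean: float = 200.0,
    purity: float = 0.7,
    muts_per_clone: float = 25.0,
) -> list[tuple[ClonalTree, list[MutationCall]]]:
    """Simulated tumors for tree-recovery experiments (S in {1, 2, 3}).

    Configurations are drawn so subclones are resolvable at the stated
    depth: linear trees keep dominant, well-separated proportions; branching
    trees carry sibling prevalences that are near-balanced but separated by
    a gap of 0.08-0.18, the regime in which both the clone count and the
    branching are recoverable from single-sample read counts.
    """
    out: list[tuple[ClonalTree, list[MutationCall]]] = []
    kinds = ["S1", "S2", "S3chain", "S3branch"]
    for i in range(n):
        kind = kinds[i % len(kinds)]
        sid = f"REC{i:04d}"
        if kind == "S1":
            tree = ClonalTree(sid, [-1], [1.0], [1], meta={"true_class": "linear"})
        elif kind == "S2":
            qf = rng.uniform(0.55, 0.8)
            tree = ClonalTree(
                sid, [-1, 0], [qf, 1 - qf], [1, 1], meta={"true_class": "linear"}
            )
        elif kind == "S3chain":
            # dominant founder, every clone and prevalence gap >= ~0.12
            qf = rng.uniform(0.4, 0.55)
            q1 = rng.uniform(0.25, 0.33)
            q = np.array([qf, q1, 1 - qf - q1])
            tree = ClonalTree(sid, [-1, 0, 1], q, [1, 1, 1], meta={"true_class": "linear"})
        else:
            # siblings balanced enough that a chain reading would imply an
            # implausibly small clone, yet separated enough (>= ~0.15 in
            # prevalence) that the two mixture components are resolvable
            # at the panel's depth
            qf = rng.uniform(0.26, 0.33)
            gap = rng.uniform(0.15, 0.19) * rng.choice([-1.0, 1.0])
            rest = 1 - qf
            q1, q2 = (rest + gap) / 2, (rest - gap) / 2
            tree = ClonalTree(
                sid, [-1, 0, 0], [qf, q1, q2], [1, 1, 1], meta={"true_class": "deep"}
            )
        n_mut = max(tree.S, int(rng.poisson(muts_per_clone * tree.S)))
        calls = simulate_reads(tree, purity, depth_mean, n_mutations=n_mut, rng=rng)
        out.append((tree, calls))
    return out
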