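"""Planted-structure benchmark: two cohesive groups plus a bipartite
pair of sparse groups, degraded by edge-rewiring noise.

The generator emulates the 128-node validation network: four groups of
32 nodes, where groups 1-2 are internally dense (cohesive modules),
groups 3-4 are internally empty but densely connected to each other (a
bi-sparse pair), and all remaining pairs carry a sparse background.
Noise rewires a fraction of edges to random non-edges, preserving the
edge count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import normalized_mutual_info_score

from .network import InteractionNetwork
from .partition import BISPARSE, COHESIVE, Partition


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of the planted-structure generator.

    Groups 1-2 are planted cohesive (intra-edge probability
    ``p_in_cohesive``); groups 3-4 are a planted bi-sparse pair:
    internally near-empty (``p_in_bipartite``) but densely linked to
    each other (``p_across_bipartite``).  Every other node pair carries
    the sparse background probability.  ``noise`` is the fraction of
    edges rewired after planting.
    """

    n_nodes: int = 128
    group_sizes: tuple[int, ...] = (32, 32, 32, 32)
    p_in_cohesive: float = 0.5
    p_across_bipartite: float = 0.5
    p_in_bipartite: float = 0.0
    p_background: float = 0.02
    noise: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.group_sizes) != self.n_nodes:
            raise ValueError("group sizes must sum to n_nodes")
        if len(self.group_sizes) != 4:
            raise ValueError("the benchmark plants exactly four groups")
        if not (0.0 <= self.noise <= 1.0):
            raise ValueError("noise must be in [0, 1]")
        for name in ("p_in_cohesive", "p_across_bipartite",
                     "p_in_bipartite", "p_background"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.p_in_cohesive <= self.p_background:
            raise ValueError("p_in_cohesive must exceed p_background")
        if self.p_across_bipartite <= self.p_background:
            raise ValueError("p_across_bipartite must exceed p_background")
        if self.p_in_bipartite > self.p_background:
            raise ValueError("p_in_bipartite must not exceed p_background")


def generate_benchmark(
    spec: BenchmarkSpec = BenchmarkSpec(),
) -> tuple[InteractionNetwork, dict[str, int]]:
    """Sample a benchmark network and its planted 4-group assignment.

    Every node pair is sampled independently with the probability the
    group pattern dictates; noise (if any) is applied afterwards with a
    seed derived from ``spec.rng_seed``.  Isolated nodes can occur and
    are retained.  Returns the network plus the ground-truth node ->
    group map (groups 0-1 cohesive, 2-3 the bi-sparse pair).
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_nodes
    group = np.repeat(np.arange(4), spec.group_sizes)
    P = np.full((4, 4), spec.p_background)
    P[0, 0] = P[1, 1] = spec.p_in_cohesive
    P[2, 2] = P[3, 3] = spec.p_in_bipartite
    P[2, 3] = P[3, 2] = spec.p_across_bipartite
    prob = P[np.ix_(group, group)]
    upper = np.triu(rng.random((n, n)) < prob, k=1)
    A = (upper | upper.T).astype(np.uint8)
    width = len(str(n - 1))
    labels = [f"n{str(i).zfill(width)}" for i in range(n)]
    network = InteractionNetwork(labels, A)
    if spec.noise > 0:
        network = add_noise(network, spec.noise, rng_seed=int(rng.integers(2**31)))
    truth = {labels[i]: int(group[i]) for i in range(n)}
    return network, truth


def add_noise(
    network: InteractionNetwork, level: float, rng_seed: int = 0
) -> InteractionNetwork:
    """Rewire ``round(level · M)`` random edges to random non-edges.

    Edges are selected uniformly without replacement and each is moved
    to a uniformly chosen non-edge, preserving the edge count with no
    self-loops or duplicates.
    """
    if not (0.0 <= level <= 1.0):
        raise ValueError("noise level must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    n = network.n_nodes
    m = network.n_edges
    n_rewire = round(level * m)
    if n_rewire == 0:
        return InteractionNetwork(network.node_labels, network.adjacency.copy())
    max_edges = n * (n - 1) // 2
    if max_edges - m < n_rewire:
        raise ValueError("not enough non-edges to absorb the rewired edges")
    A = network.adjacency.copy()
    original = network.adjacency  # untouched copy for the non-edge test
    ii, jj = np.nonzero(np.triu(A, k=1))
    picked = rng.choice(ii.size, size=n_rewire, replace=False)
    for e in picked:
        A[ii[e], jj[e]] = A[jj[e], ii[e]] = 0
    for _ in range(n_rewire):
        # target must be a non-edge of the original network too, so the
        # requested number of original edges is really replaced
        while True:
            u, v = rng.integers(n, size=2)
            if u != v and not A[u, v] and not original[u, v]:
                break
        A[u, v] = A[v, u] = 1
    return InteractionNetwork(network.node_labels, A)


@dataclass
class RecoveryReport:
    """How well a detected partition matches the planted assignment."""

    n_modules_found: int
    n_modules_true: int
    nmi: float
    jaccard_by_group: dict[int, float] = field(default_factory=dict)

    @property
    def module_count_difference(self) -> int:
        return self.n_modules_found - self.n_modules_true


def score_recovery(found: Partition, truth: dict[str, int]) -> RecoveryReport:
    """Score a partition against ground truth: NMI and per-group Jaccard.

    The NMI is the standard contingency-table normalised mutual
    information over node labels; each planted group additionally
    reports its best Jaccard overlap with any found module.
    """
    assignment = found.assignment()
    if set(assignment) != set(truth):
        raise ValueError("found partition and truth cover different node sets")
    nodes = sorted(truth)
    y_true = [truth[v] for v in nodes]
    y_found = [assignment[v] for v in nodes]
    nmi = float(normalized_mutual_info_score(y_true, y_found))
    groups: dict[int, set[str]] = {}
    for v, g in truth.items():
        groups.setdefault(g, set()).add(v)
    jaccard = {}
    for g, members in groups.items():
        best = 0.0
        for mod in found.modules:
            inter = len(members & mod.members)
            union = len(members | mod.members)
            best = max(best, inter / union)
        jaccard[g] = best
    true_ids = set(truth.values())
    return RecoveryReport(
        n_modules_found=found.n_modules,
        n_modules_true=len(true_ids),
        nmi=nmi,
        jaccard_by_group=jaccard,
    )


def truth_partition(truth: dict[str, int], network: InteractionNetwork) -> Partition:
    """Wrap a ground-truth assignment as a Partition (groups 0-1 cohesive)."""
    from .partition import Module
    from . import metrics

    modules = []
    for g in sorted(set(truth.values())):
        members = frozenset(v for v, gg in truth.items() if gg == g)
        mtype = COHESIVE if g in (0, 1) else BISPARSE
        modules.append(
            Module(id=g, members=members, mtype=mtype,
                   edm=metrics.edm(network, members))
        )
    return Partition(modules=modules)
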