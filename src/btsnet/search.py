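"""BinTree Seeking: greedy growth of cohesive and bi-sparse modules
explored over a binary tree of extraction orders.

The search maintains a set of partial states.  Each state holds the
modules extracted so far and the residual node set.  Expanding a state
produces up to two kinds of children: a *cohesive* child, obtained by
growing a module of high internal link density (LD >= a1) around a seed
and pruning low-LD members, and a *bi-sparse* child, obtained by growing
a module of very low internal link density (LD <= a2) and keeping only
members densely bridged (EDBM/LD >= a3) to previously extracted modules.
Bridges between modules are recorded whenever their bipartite edge
density reaches a3.  A root-to-leaf path is a complete partition; leaves
are scored by the block-model error E under their fitted image graph and
the minimum-E leaf wins, which is how the number of modules is chosen
automatically.

The tree is explored with a deduplicated beam keyed by the E of the
partial partition (residual nodes pooled as one provisional block);
small networks get a wider beam so that on structured inputs all
distinct states are visited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Iterable, Sequence

import numpy as np

from . import metrics
from .network import InteractionNetwork
from .partition import BISPARSE, COHESIVE, BridgeMatrix, Module, Partition, Thresholds
from .quality import ImageGraph, error_e, fit_image_graph, modularity_q

logger = logging.getLogger(__name__)

_SMALL_NETWORK = 200  # below this, the beam widens automatically
_WIDE_BEAM = 32


# ---------------------------------------------------------------------------
# default thresholds and low-level greedy operations
# ---------------------------------------------------------------------------


def default_thresholds(network: InteractionNetwork) -> Thresholds:
    """Data-driven thresholds anchored at the network's own edge density.

    a3 is set to EDN; a1 = min(10·a3, 0.5) (lifted above a3 if the
    network is very dense) and a2 = a3/10, which keeps a1 > a3 > a2 with
    a1 < 1 and a2 > 0 by construction.
    """
    density = metrics.edn(network)
    if density == 0:
        raise ValueError(
            "edgeless network: automatic thresholds are undefined, "
            "pass explicit (a1, a2, a3)"
        )
    a3 = density
    a1 = min(10.0 * a3, 0.5)
    if a1 <= a3:
        a1 = (1.0 + a3) / 2.0  # very dense network; keep a1 in (a3, 1)
    a2 = a3 / 10.0
    return Thresholds(a1=a1, a2=a2, a3=a3)


def _neighbour_overlap(A: np.ndarray, member_idx: np.ndarray) -> np.ndarray:
    """Per-node count of shared neighbours with the module's neighbourhood."""
    nbr = A[member_idx].any(axis=0).astype(A.dtype)
    return A @ nbr


def _grow(
    A: np.ndarray,
    residual: np.ndarray,
    seed: int,
    threshold: float,
    cohesive: bool,
) -> np.ndarray:
    """Greedy best-first growth from a seed; returns member indices.

    Cohesive mode adds the residual node of highest link density to the
    current members while that density exceeds ``threshold``; bi-sparse
    mode adds the lowest-density node while it stays below ``threshold``.
    Exact ties are broken by the candidate's shared-neighbour count with
    the module (structurally equivalent nodes first), then by label.
    """
    n = A.shape[0]
    in_res = np.zeros(n, dtype=bool)
    in_res[residual] = True
    if not in_res[seed]:
        raise ValueError("seed is not in the residual node set")
    member = np.zeros(n, dtype=bool)
    member[seed] = True
    members = [seed]
    # edges from every node into the module, maintained incrementally
    cnt = A[seed].astype(np.int64).copy()
    while True:
        cand = in_res & ~member
        if not cand.any():
            break
        k = len(members)
        cand_idx = np.nonzero(cand)[0]
        cand_cnt = cnt[cand_idx]
        if cohesive:
            ok = cand_cnt >= threshold * k  # a1 is an inclusive lower limit
            best_cnt = cand_cnt.max() if ok.any() else None
        else:
            ok = cand_cnt <= threshold * k  # a2 is an inclusive upper limit
            best_cnt = cand_cnt.min() if ok.any() else None
        if best_cnt is None:
            break
        tied = cand_idx[ok & (cand_cnt == best_cnt)]
        if tied.size > 1:
            overlap = _neighbour_overlap(A, np.array(members))[tied]
            tied = tied[overlap == overlap.max()]
        chosen = int(tied[0])  # label order: canonical index = sorted label
        member[chosen] = True
        members.append(chosen)
        cnt += A[chosen]
    return np.array(sorted(members), dtype=np.intp)


def _refine_cohesive(
    A: np.ndarray, member_idx: np.ndarray, a1: float
) -> tuple[np.ndarray, np.ndarray]:
    """Expel low-LD members; returns (kept, expelled) index arrays."""
    members = list(member_idx)
    expelled: list[int] = []
    while len(members) >= 2:
        idx = np.array(members)
        sub = A[np.ix_(idx, idx)]
        cnt = sub.sum(axis=1)
        k = len(members) - 1
        worst = int(np.argmin(cnt))  # ties: lowest index = label order
        if cnt[worst] < a1 * k:  # strictly below the lower limit
            expelled.append(members.pop(worst))
        else:
            break
    if len(members) < 2:
        expelled.extend(members)
        members = []
    return np.array(sorted(members), dtype=np.intp), np.array(
        sorted(expelled), dtype=np.intp
    )


def _regulate_bisparse(
    A: np.ndarray,
    member_idx: np.ndarray,
    partner_blocks: Sequence[np.ndarray],
    a3: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Keep members densely linked to at least one bridge partner.

    A member is kept when its best link density towards any bridge
    partner reaches a3; with no partners the module is left unchanged.
    """
    if not partner_blocks:
        return member_idx, np.array([], dtype=np.intp)
    best = np.zeros(member_idx.size)
    for block in partner_blocks:
        ld = A[np.ix_(member_idx, block)].sum(axis=1) / block.size
        best = np.maximum(best, ld)
    keep = best >= a3
    return member_idx[keep], member_idx[~keep]


# ---------------------------------------------------------------------------
# label-level wrappers for the greedy operations
# ---------------------------------------------------------------------------


def grow_cohesive(
    network: InteractionNetwork,
    residual: Iterable[str],
    seed: str,
    a1: float,
) -> Module:
    """Grow a cohesive module from ``seed`` inside ``residual`` (LD >= a1).

    A seed with no qualifying neighbour yields a singleton, which is
    re-tagged bi-sparse (a single node has no internal density).
    """
    res_idx = network.indices_of(residual)
    idx = _grow(network.adjacency, res_idx, network.index_of(seed), a1, cohesive=True)
    members = frozenset(network.node_labels[i] for i in idx)
    mtype = COHESIVE if len(members) > 1 else BISPARSE
    return Module(id=0, members=members, mtype=mtype, edm=metrics.edm(network, members))


def grow_bisparse(
    network: InteractionNetwork,
    residual: Iterable[str],
    seed: str,
    a2: float,
) -> Module:
    """Grow a bi-sparse module from ``seed`` inside ``residual`` (LD <= a2)."""
    res_idx = network.indices_of(residual)
    idx = _grow(network.adjacency, res_idx, network.index_of(seed), a2, cohesive=False)
    members = frozenset(network.node_labels[i] for i in idx)
    return Module(id=0, members=members, mtype=BISPARSE, edm=metrics.edm(network, members))


def build_bridges(
    network: InteractionNetwork,
    module: Module,
    others: Sequence[Module],
    a3: float,
) -> list[BridgeMatrix]:
    """Record a bridge to every other module whose EDBM reaches a3."""
    bridges = []
    for other in others:
        if module.members & other.members:
            raise ValueError("modules must be disjoint")
        density = metrics.edbm(network, module.members, other.members)
        if density >= a3:
            bridges.append(
                BridgeMatrix(module_a=module.id, module_b=other.id, edbm=density)
            )
    return bridges


def refine_cohesive(
    network: InteractionNetwork, module: Module, a1: float
) -> tuple[Module | None, frozenset[str]]:
    """Iteratively expel the lowest-LD member while its LD < a1.

    Returns the refined module (or None if it dissolved below two
    members) and the expelled node set.
    """
    if module.mtype != COHESIVE:
        raise ValueError("refine_cohesive expects a cohesive module")
    idx = network.indices_of(module.members)
    kept, expelled = _refine_cohesive(network.adjacency, idx, a1)
    expelled_labels = frozenset(network.node_labels[i] for i in expelled)
    if kept.size == 0:
        return None, expelled_labels
    members = frozenset(network.node_labels[i] for i in kept)
    return (
        Module(id=module.id, members=members, mtype=COHESIVE,
               edm=metrics.edm(network, members)),
        expelled_labels,
    )


def regulate_bisparse(
    network: InteractionNetwork,
    module: Module,
    partners: Sequence[Module],
    a3: float,
) -> tuple[Module | None, frozenset[str]]:
    """Expel members whose best link density to any bridge partner is < a3."""
    if module.mtype != BISPARSE:
        raise ValueError("regulate_bisparse expects a bi-sparse module")
    idx = network.indices_of(module.members)
    blocks = [network.indices_of(p.members) for p in partners]
    kept, expelled = _regulate_bisparse(network.adjacency, idx, blocks, a3)
    expelled_labels = frozenset(network.node_labels[i] for i in expelled)
    if kept.size == 0:
        return None, expelled_labels
    members = frozenset(network.node_labels[i] for i in kept)
    return (
        Module(id=module.id, members=members, mtype=BISPARSE,
               edm=metrics.edm(network, members)),
        expelled_labels,
    )


# ---------------------------------------------------------------------------
# block-level scoring helpers (index arrays, no label dictionaries)
# ---------------------------------------------------------------------------


def _block_error(
    A: np.ndarray, deg: np.ndarray, m: int, blocks: Sequence[np.ndarray]
) -> tuple[np.ndarray, float]:
    """Fitted image graph and selection score for a list of index blocks.

    The score is the pairwise block-model error over node pairs i < j,

        -(sum over blocks with B=1 of observed minus expected edges),

    with the configuration null restricted to distinct pairs.  Under
    this form splitting a homogeneous block (image graph extended over
    the pieces) changes nothing — the over-split indifference — so the
    search cannot gain by shattering a module, and equal scores resolve
    to the coarser partition.  The reported E of a final partition is
    the self-pair-inclusive Hamiltonian of :func:`btsnet.quality.error_e`
    (the one that reduces to -M·Q on diagonal image graphs); the two
    forms rank genuinely different block structures identically.
    """
    q = len(blocks)
    n = A.shape[0]
    S = np.zeros((n, q))
    for r, blk in enumerate(blocks):
        S[blk, r] = 1.0
    W = S.T @ A @ S
    if m == 0:
        return np.zeros((q, q), dtype=int), 0.0
    D = deg @ S
    sumsq = (deg.astype(np.float64) ** 2) @ S
    null = np.outer(D, D) / (2.0 * m)
    np.fill_diagonal(null, (D**2 - sumsq) / (2.0 * m))  # i<j pairs only
    B = (W > null).astype(int)
    return B, float(-0.5 * np.sum((W - null) * B))


# ---------------------------------------------------------------------------
# the tree search
# ---------------------------------------------------------------------------


@dataclass
class _State:
    residual: frozenset[int]
    blocks: tuple[tuple[frozenset[int], str], ...]  # (members, mtype) in order
    score: float = 0.0

    def key(self) -> tuple:
        return (self.residual, frozenset(self.blocks))


@dataclass
class _SearchLog:
    expansions: int = 0
    leaves: int = 0
    pruned: int = 0


def _pick_seeds(
    A: np.ndarray,
    residual: np.ndarray,
    n_seeds: int,
    cohesive_branch: bool,
    policy: str,
    rng: np.random.Generator,
) -> list[int]:
    """Seed choice per branch.

    The default ``clustering`` policy scores residual nodes by their
    local clustering coefficient in the residual-induced subgraph
    (degree as tie-break, then label): cohesive seeds are the most
    locally clustered nodes, bi-sparse seeds the least.  A clique member
    sits in many residual triangles while a member of a bipartite-paired
    sparse group sits in almost none, so clustering separates the two
    roles even when raw degrees coincide.
    """
    if policy == "random":
        k = min(n_seeds, residual.size)
        return [int(s) for s in rng.choice(residual, size=k, replace=False)]
    sub = A[np.ix_(residual, residual)].astype(np.float64)
    deg = sub.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", sub, sub, sub) / 2.0
    denom = np.maximum(deg * (deg - 1) / 2.0, 1.0)
    clust = triangles / denom
    if cohesive_branch:
        order = np.lexsort((residual, -deg, -clust))
    else:
        order = np.lexsort((residual, deg, clust))
    return [int(residual[i]) for i in order[: min(n_seeds, residual.size)]]


def bts_search(
    network: InteractionNetwork,
    thresholds: Thresholds | None = None,
    n_seeds: int = 2,
    beam: int | None = None,
    rng_seed: int = 0,
    seed_policy: str = "clustering",
) -> Partition:
    """Run the full BinTree search and return the minimum-E partition.

    Parameters mirror :class:`BinTreeSeeking`; see its docstring.
    """
    if network.n_nodes == 0:
        raise ValueError("empty network")
    if thresholds is None:
        thresholds = default_thresholds(network)
    else:  # re-validate: callers may hand over a mutated/foreign object
        thresholds = Thresholds(a1=thresholds.a1, a2=thresholds.a2, a3=thresholds.a3)
    if seed_policy not in ("clustering", "random"):
        raise ValueError(f"unknown seed policy {seed_policy!r}")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    a1, a2, a3 = thresholds.a1, thresholds.a2, thresholds.a3
    Ai = network.adjacency
    deg = network.degrees()
    m = network.n_edges
    n = network.n_nodes
    if beam is None:
        beam = _WIDE_BEAM if n < _SMALL_NETWORK else 8
    rng = np.random.default_rng(rng_seed)
    log = _SearchLog()

    def partial_score(state: _State) -> float:
        blocks = [np.fromiter(b, dtype=np.intp) for b, _ in state.blocks]
        if state.residual:
            blocks.append(np.fromiter(state.residual, dtype=np.intp))
        _, e = _block_error(Ai, deg, m, blocks)
        return e

    def expand(state: _State) -> list[_State]:
        log.expansions += 1
        residual = np.fromiter(sorted(state.residual), dtype=np.intp)
        existing = [np.fromiter(sorted(b), dtype=np.intp) for b, _ in state.blocks]
        children: list[_State] = []

        def bridge_partners(member_idx: np.ndarray) -> list[int]:
            partners = []
            for bi, block in enumerate(existing):
                dens = Ai[np.ix_(member_idx, block)].sum() / (
                    member_idx.size * block.size
                )
                if dens >= a3:
                    partners.append(bi)
            return partners

        def add_child(member_idx: np.ndarray, mtype: str) -> None:
            members = frozenset(int(i) for i in member_idx)
            child = _State(
                residual=state.residual - members,
                blocks=state.blocks + ((members, mtype),),
            )
            child.score = partial_score(child)
            children.append(child)

        coh_seeds = _pick_seeds(Ai, residual, n_seeds, True, seed_policy, rng)
        bis_seeds = _pick_seeds(Ai, residual, n_seeds, False, seed_policy, rng)

        for seed in coh_seeds:
            grown = _grow(Ai, residual, seed, a1, cohesive=True)
            if grown.size < 2:
                continue  # singleton: the bi-sparse branch covers it
            kept, _ = _refine_cohesive(Ai, grown, a1)
            if kept.size >= 2:
                add_child(kept, COHESIVE)

        for seed in bis_seeds:
            grown = _grow(Ai, residual, seed, a2, cohesive=False)
            partners = bridge_partners(grown)
            blocks = [existing[i] for i in partners]
            kept, _ = _regulate_bisparse(Ai, grown, blocks, a3)
            if kept.size == 0:
                kept = np.array([seed], dtype=np.intp)  # guarantee progress
            add_child(kept, BISPARSE)
        return children

    root = _State(residual=frozenset(range(n)), blocks=())
    frontier = [root]
    leaves: list[_State] = []
    while frontier:
        next_frontier: dict[tuple, _State] = {}
        for state in frontier:
            for child in expand(state):
                if not child.residual:
                    leaves.append(child)
                    log.leaves += 1
                else:
                    key = child.key()
                    if key not in next_frontier:
                        next_frontier[key] = child
        ranked = sorted(next_frontier.values(), key=lambda s: s.score)
        log.pruned += max(0, len(ranked) - beam)
        frontier = ranked[:beam]

    # score each leaf with its fitted image graph and keep the best E;
    # scores within float tolerance count as ties, resolved to the
    # coarser partition (the over-split indifference makes exact ties common)
    def leaf_score(i: int) -> tuple[float, int, int]:
        blocks = [np.fromiter(sorted(b), dtype=np.intp) for b, _ in leaves[i].blocks]
        _, e = _block_error(Ai, deg, m, blocks)
        return (e, len(blocks), i)

    scored = [leaf_score(i) for i in range(len(leaves))]
    e_min = min(e for e, _, _ in scored)
    tol = 1e-9 * max(1.0, abs(e_min))
    best = min((s for s in scored if s[0] <= e_min + tol),
               key=lambda s: (s[1], s[2]))
    winner = leaves[best[2]]
    logger.debug(
        "BTS search: %d expansions, %d leaves, best E=%.6g with %d modules",
        log.expansions, log.leaves, best[0], len(winner.blocks),
    )
    return _finalise(network, winner, thresholds)


def _finalise(
    network: InteractionNetwork, leaf: _State, thresholds: Thresholds
) -> Partition:
    """Turn a winning leaf into a Partition with bridges, E, Q and image graph."""
    labels = network.node_labels
    modules = []
    for mid, (block, mtype) in enumerate(leaf.blocks):
        members = frozenset(labels[i] for i in block)
        modules.append(
            Module(id=mid, members=members, mtype=mtype,
                   edm=metrics.edm(network, members))
        )
    bridges = []
    for i, mod in enumerate(modules):
        for other in modules[i + 1:]:
            density = metrics.edbm(network, mod.members, other.members)
            if density >= thresholds.a3:
                bridges.append(BridgeMatrix(mod.id, other.id, density))
    assignment = {lab: mod.id for mod in modules for lab in mod.members}
    induced = _induced_image(modules, bridges)
    fitted = fit_image_graph(network, assignment)
    if not np.array_equal(induced.B, fitted.B):
        logger.debug(
            "induced image graph differs from fitted one on %d entries",
            int(np.abs(induced.B - fitted.B).sum()),
        )
    e = error_e(network, assignment, fitted)
    q = modularity_q(network, assignment) if network.n_edges else float("nan")
    return Partition(modules=modules, bridges=bridges, error=e, modularity=q)


def _induced_image(
    modules: Sequence[Module], bridges: Sequence[BridgeMatrix]
) -> ImageGraph:
    """Image graph read off module types (diagonal) and bridges (off-diagonal)."""
    ids = tuple(mod.id for mod in modules)
    pos = {mid: i for i, mid in enumerate(ids)}
    B = np.zeros((len(ids), len(ids)), dtype=int)
    for mod in modules:
        B[pos[mod.id], pos[mod.id]] = 1 if mod.mtype == COHESIVE else 0
    for br in bridges:
        B[pos[br.module_a], pos[br.module_b]] = 1
        B[pos[br.module_b], pos[br.module_a]] = 1
    return ImageGraph(ids, B)


def threshold_sweep(
    network: InteractionNetwork,
    a1_grid: Sequence[float],
    a2_grid: Sequence[float],
    rng_seed: int = 0,
    **search_kwargs,
):
    """Run the search over a grid of (a1, a2) with a3 fixed at EDN.

    Returns a DataFrame with columns a1, a2, E, Q, n_modules; grid
    points violating a1 > a3 > a2 are skipped with a warning.
    """
    import pandas as pd

    a3 = metrics.edn(network)
    rows = []
    for a1 in a1_grid:
        for a2 in a2_grid:
            try:
                th = Thresholds(a1=a1, a2=a2, a3=a3)
            except ValueError as exc:
                logger.warning("skipping grid point (a1=%g, a2=%g): %s", a1, a2, exc)
                continue
            part = bts_search(network, th, rng_seed=rng_seed, **search_kwargs)
            rows.append(
                {"a1": a1, "a2": a2, "E": part.error, "Q": part.modularity,
                 "n_modules": part.n_modules}
            )
    return pd.DataFrame(rows, columns=["a1", "a2", "E", "Q", "n_modules"])
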