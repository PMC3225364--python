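"""Edge-density statistics: EDM, LD, EDBM and EDN.

These four statistics are the primitives the BinTree search is built on.
For a module r with n_r nodes and L_r internal edges,

    EDM(r)      = 2 L_r / (n_r (n_r - 1))          (simple-graph density)
    LD(v, r)    = |N(v) ∩ r \\ {v}| / |r \\ {v}|     (neighbour fraction)
    EDBM(r, s)  = L_rs / (n_r n_s)                 (bipartite density)
    EDN(R)      = 2 L_R / (N (N - 1))              (whole-network density)

All values lie in [0, 1] and are invariant under any relabeling of the
node order.  A singleton module has EDM 0 by convention (it has no
internal edge capacity), which classifies singletons as bi-sparse.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np

from .network import InteractionNetwork


def _member_indices(network: InteractionNetwork, members: Iterable[str]) -> np.ndarray:
    idx = network.indices_of(members)
    if idx.size == 0:
        raise ValueError("member set must be nonempty")
    if len(set(idx.tolist())) != idx.size:
        raise ValueError("duplicate members")
    return idx


def internal_edge_count(network: InteractionNetwork, members: Iterable[str]) -> int:
    """L_r: number of edges with both endpoints in ``members``."""
    idx = _member_indices(network, members)
    sub = network.adjacency[np.ix_(idx, idx)]
    return int(sub.sum()) // 2


def edm(network: InteractionNetwork, members: Iterable[str]) -> float:
    """Edge Density of Module: realized fraction of possible internal edges."""
    idx = _member_indices(network, members)
    n = idx.size
    if n == 1:
        return 0.0
    sub = network.adjacency[np.ix_(idx, idx)]
    l_r = int(sub.sum()) // 2
    return 2.0 * l_r / (n * (n - 1))


def link_density(
    network: InteractionNetwork, v: str, members: Iterable[str]
) -> float:
    """Link Density: fraction of ``members`` adjacent to node ``v``.

    If ``v`` itself is in ``members`` it is excluded from both the
    neighbour count and the denominator, so the value is a proper
    neighbour fraction in [0, 1].
    """
    vi = network.index_of(v)
    idx = _member_indices(network, members)
    idx = idx[idx != vi]
    if idx.size == 0:
        raise ValueError("empty reference set: members contain only v")
    return float(network.adjacency[vi, idx].sum()) / idx.size


def edbm(
    network: InteractionNetwork,
    members_r: Iterable[str],
    members_s: Iterable[str],
) -> float:
    """Edge Density of Bridge Matrix between two disjoint modules."""
    idx_r = _member_indices(network, members_r)
    idx_s = _member_indices(network, members_s)
    if np.intersect1d(idx_r, idx_s).size:
        raise ValueError("modules must be disjoint")
    l_rs = int(network.adjacency[np.ix_(idx_r, idx_s)].sum())
    return l_rs / (idx_r.size * idx_s.size)


def edn(network: InteractionNetwork) -> float:
    """Edge Density of the whole Network; equals EDM over all nodes."""
    n = network.n_nodes
    if n < 2:
        raise ValueError("EDN requires at least 2 nodes")
    return 2.0 * network.n_edges / (n * (n - 1))
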