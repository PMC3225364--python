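"""Canonical in-memory representation of an interaction network.

A protein interaction network (PIN) is stored as an ordered list of node
labels plus a symmetric, binary, zero-diagonal adjacency matrix.  All
statistics and the BinTree search operate on this object.  Node order is
lexicographic on labels so that every downstream matrix operation is
reproducible regardless of the order edges appear in an input file.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import networkx as nx
import numpy as np


class InteractionNetwork:
    """Undirected, unweighted interaction network.

    Parameters
    ----------
    node_labels : sequence of str
        Unique node identifiers in the canonical (sorted) order.
    adjacency : ndarray of shape (N, N)
        Symmetric binary matrix with zero diagonal.

    Attributes
    ----------
    n_nodes : int
        Number of nodes N.
    n_edges : int
        Number of undirected edges M.
    """

    def __init__(self, node_labels: Sequence[str], adjacency: np.ndarray):
        labels = list(node_labels)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate node labels")
        A = np.asarray(adjacency)
        if A.shape != (len(labels), len(labels)):
            raise ValueError(
                f"adjacency shape {A.shape} does not match {len(labels)} labels"
            )
        A = (A != 0).astype(np.uint8)
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A)):
            raise ValueError("adjacency must have zero diagonal (no self-loops)")
        self.node_labels: list[str] = labels
        self.adjacency: np.ndarray = A
        self._index = {lab: i for i, lab in enumerate(labels)}

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], extra_nodes: Iterable[str] = ()
    ) -> "InteractionNetwork":
        """Build a network from an iterable of label pairs.

        Self-loops are dropped and duplicate/reversed edges collapsed; node
        order is lexicographic on labels.
        """
        pairs = set()
        nodes = set(extra_nodes)
        for u, v in edges:
            u, v = str(u), str(v)
            nodes.add(u)
            nodes.add(v)
            if u == v:
                continue  # self-links removed on load
            pairs.add((u, v) if u < v else (v, u))
        labels = sorted(nodes)
        index = {lab: i for i, lab in enumerate(labels)}
        A = np.zeros((len(labels), len(labels)), dtype=np.uint8)
        for u, v in pairs:
            i, j = index[u], index[v]
            A[i, j] = A[j, i] = 1
        return cls(labels, A)

    @classmethod
    def from_networkx(cls, graph: nx.Graph) -> "InteractionNetwork":
        net = cls.from_edges(
            ((str(u), str(v)) for u, v in graph.edges()),
            extra_nodes=(str(u) for u in graph.nodes()),
        )
        return net

    # -- basic properties -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown node: {label!r}") from None

    def indices_of(self, labels: Iterable[str]) -> np.ndarray:
        return np.fromiter(
            (self.index_of(l) for l in labels), dtype=np.intp
        )

    def degrees(self) -> np.ndarray:
        """Degree vector k in canonical node order."""
        return self.adjacency.sum(axis=1).astype(np.int64)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        ii, jj = np.nonzero(np.triu(self.adjacency))
        g.add_edges_from(
            (self.node_labels[i], self.node_labels[j]) for i, j in zip(ii, jj)
        )
        return g

    def edge_set(self) -> set[tuple[str, str]]:
        """Edges as a set of sorted label pairs."""
        ii, jj = np.nonzero(np.triu(self.adjacency))
        return {
            (self.node_labels[i], self.node_labels[j]) for i, j in zip(ii, jj)
        }

    def __repr__(self) -> str:  # pragma: no cover
        return f"InteractionNetwork(N={self.n_nodes}, M={self.n_edges})"
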