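"""Partition quality: Newman modularity Q and the block-model error E.

The error function scores how well a partition, together with a binary
image graph B, reproduces the observed adjacency against a
degree-preserving (configuration-model) null:

    E = -(1/2) Σ_ij (A_ij - k_i k_j / 2M) B[σ_i][σ_j]

where σ_i is node i's module and B[r][s] = 1 declares the (r, s) block
link-dense.  Lower E is better.  B's diagonal distinguishes module
types: B[r][r] = 1 describes a cohesive module, B[r][r] = 0 a bi-sparse
one; off-diagonal ones are dense bridges.  For a purely diagonal image
graph E reduces exactly to -M·Q, so modularity maximisation is the
special case in which only cohesive structure is rewarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping

import numpy as np

from .network import InteractionNetwork


@dataclass(frozen=True)
class ImageGraph:
    """Binary q×q block pattern over modules.

    ``module_ids`` maps matrix rows/columns to module identifiers.
    """

    module_ids: tuple[int, ...]
    B: np.ndarray

    def __post_init__(self) -> None:
        B = np.asarray(self.B)
        if B.shape != (len(self.module_ids), len(self.module_ids)):
            raise ValueError("B shape does not match module_ids")
        if not np.array_equal(B, B.T):
            raise ValueError("image graph must be symmetric")
        if not np.isin(B, (0, 1)).all():
            raise ValueError("image graph must be binary")

    @property
    def q(self) -> int:
        return len(self.module_ids)

    def row_of(self, module_id: int) -> int:
        return self.module_ids.index(module_id)


def _block_stats(
    network: InteractionNetwork, assignment: Mapping[str, int]
) -> tuple[tuple[int, ...], np.ndarray, np.ndarray, int]:
    """Per-block edge counts W (W_rr = 2 L_r) and degree sums D."""
    missing = [lab for lab in network.node_labels if lab not in assignment]
    if missing:
        raise ValueError(f"assignment misses nodes: {', '.join(missing[:5])}")
    ids = sorted({assignment[lab] for lab in network.node_labels})
    pos = {mid: r for r, mid in enumerate(ids)}
    sigma = np.array(
        [pos[assignment[lab]] for lab in network.node_labels], dtype=np.intp
    )
    q = len(ids)
    S = np.zeros((network.n_nodes, q))
    S[np.arange(network.n_nodes), sigma] = 1.0
    W = S.T @ network.adjacency @ S  # W_rs = sum of A over the (r,s) block
    D = network.degrees() @ S  # total degree per block
    return tuple(ids), W, D, network.n_edges


def modularity_q(
    network: InteractionNetwork, assignment: Mapping[str, int]
) -> float:
    """Newman modularity Q = Σ_r [ L_r/M - (D_r/2M)² ]."""
    _, W, D, m = _block_stats(network, assignment)
    if m == 0:
        raise ValueError("modularity is undefined for an edgeless network")
    l_r = np.diag(W) / 2.0
    return float(np.sum(l_r / m - (D / (2.0 * m)) ** 2))


def fit_image_graph(
    network: InteractionNetwork, assignment: Mapping[str, int]
) -> ImageGraph:
    """E-minimising image graph for a fixed assignment.

    Sets B[r][s] = 1 exactly when the observed edge mass of the (r, s)
    block exceeds its configuration-null expectation; every block then
    contributes a non-positive term to E.
    """
    ids, W, D, m = _block_stats(network, assignment)
    if m == 0:
        B = np.zeros((len(ids), len(ids)), dtype=int)
        return ImageGraph(ids, B)
    null = np.outer(D, D) / (2.0 * m)
    B = (W > null).astype(int)
    return ImageGraph(ids, B)


def error_e(
    network: InteractionNetwork,
    assignment: Mapping[str, int],
    image: ImageGraph,
) -> float:
    """Block-model error E of the partition under image graph B (lower wins)."""
    ids, W, D, m = _block_stats(network, assignment)
    if set(ids) != set(image.module_ids):
        raise ValueError("image graph module ids do not match the assignment")
    order = [image.row_of(mid) for mid in ids]
    B = np.asarray(image.B)[np.ix_(order, order)]
    if m == 0:
        return 0.0
    null = np.outer(D, D) / (2.0 * m)
    return float(-0.5 * np.sum((W - null) * B))
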