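"""scikit-learn style estimator wrapping the BinTree search."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin

from .network import InteractionNetwork
from .partition import Thresholds
from .search import bts_search, default_thresholds


class BinTreeSeeking(ClusterMixin, BaseEstimator):
    """Detect cohesive and bi-sparse modules in an interaction network.

    The estimator clusters the nodes of an undirected, unweighted graph
    into modules that are either *cohesive* (dense inside) or
    *bi-sparse* (sparse inside but densely bridged to other modules),
    by greedily growing both kinds of module from seeds over a binary
    tree of extraction orders and returning the complete partition with
    the lowest block-model error E.  The number of modules is determined
    automatically by that selection.

    Parameters
    ----------
    a1, a2, a3 : float or None, default None
        Growth/bridge thresholds (cohesive LD lower limit, bi-sparse LD
        upper limit, bridge EDBM lower limit), required to satisfy
        ``a1 > a3 > a2`` with ``a1 < 1`` and ``a2 > 0``.  When all three
        are None they are derived from the network's edge density
        (a3 = EDN, a1 = min(10·a3, 0.5), a2 = a3/10).
    n_seeds : int, default 2
        Seeds tried per branch at every tree node.
    beam_width : int or None, default None
        Beam width of the tree search; None picks 32 for networks below
        200 nodes and 8 otherwise.
    seed_policy : {"clustering", "random"}, default "clustering"
        Seed choice per branch: the most locally clustered residual node
        for the cohesive branch and the least clustered for the
        bi-sparse branch (degree, then label, as tie-breaks), or
        uniform random.
    random_state : int, default 0
        Seed for all stochastic choices (only used by the random policy;
        kept for reproducibility contracts either way).

    Attributes
    ----------
    labels_ : ndarray of shape (n_nodes,)
        Module index per node, in the canonical (sorted-label) order.
    module_types_ : list of str
        ``"cohesive"`` or ``"bi-sparse"`` per module index.
    partition_ : Partition
        Full result: modules, bridges, error E and modularity Q.
    thresholds_ : Thresholds
        Thresholds actually used.
    error_ : float
        Block-model error E of the selected partition (lower is better).
    modularity_ : float
        Newman modularity Q of the selected partition.
    n_modules_ : int
        Number of detected modules.
    network_ : InteractionNetwork
        The canonical network the model was fitted on.

    Examples
    --------
    >>> from btsnet import BinTreeSeeking, generate_benchmark, BenchmarkSpec
    >>> net, truth = generate_benchmark(BenchmarkSpec(rng_seed=0))
    >>> model = BinTreeSeeking().fit(net)
    >>> model.n_modules_  # doctest: +SKIP
    4
    """

    def __init__(
        self,
        a1: float | None = None,
        a2: float | None = None,
        a3: float | None = None,
        n_seeds: int = 2,
        beam_width: int | None = None,
        seed_policy: str = "clustering",
        random_state: int = 0,
    ):
        self.a1 = a1
        self.a2 = a2
        self.a3 = a3
        self.n_seeds = n_seeds
        self.beam_width = beam_width
        self.seed_policy = seed_policy
        self.random_state = random_state

    # ------------------------------------------------------------------

    @staticmethod
    def _as_network(X) -> InteractionNetwork:
        if isinstance(X, InteractionNetwork):
            return X
        try:
            import networkx as nx

            if isinstance(X, nx.Graph):
                return InteractionNetwork.from_networkx(X)
        except ImportError:  # pragma: no cover
            pass
        if sp.issparse(X):
            X = X.toarray()
        A = np.asarray(X)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(
                "X must be an InteractionNetwork, a networkx Graph or a "
                f"square adjacency matrix, got shape {getattr(A, 'shape', None)}"
            )
        n = A.shape[0]
        width = len(str(n - 1)) if n else 1
        labels = [f"n{str(i).zfill(width)}" for i in range(n)]
        A = np.asarray(A != 0, dtype=np.uint8)
        np.fill_diagonal(A, 0)
        return InteractionNetwork(labels, np.maximum(A, A.T))

    def _resolve_thresholds(self, network: InteractionNetwork) -> Thresholds:
        given = (self.a1, self.a2, self.a3)
        if all(v is None for v in given):
            return default_thresholds(network)
        if any(v is None for v in given):
            raise ValueError("set all of a1, a2, a3 or none of them")
        return Thresholds(a1=self.a1, a2=self.a2, a3=self.a3)

    def fit(self, X, y=None):
        """Run the BinTree search on a network.

        Parameters
        ----------
        X : InteractionNetwork, networkx.Graph or (n, n) array-like
            The network to cluster; array input is binarised and
            symmetrised, with the diagonal zeroed.
        y : ignored
        """
        network = self._as_network(X)
        thresholds = self._resolve_thresholds(network)
        partition = bts_search(
            network,
            thresholds,
            n_seeds=self.n_seeds,
            beam=self.beam_width,
            rng_seed=self.random_state,
            seed_policy=self.seed_policy,
        )
        assignment = partition.assignment()
        self.network_ = network
        self.thresholds_ = thresholds
        self.partition_ = partition
        self.labels_ = np.array(
            [assignment[lab] for lab in network.node_labels], dtype=np.intp
        )
        self.module_types_ = [m.mtype for m in partition.modules]
        self.error_ = partition.error
        self.modularity_ = partition.modularity
        self.n_modules_ = partition.n_modules
        return self
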